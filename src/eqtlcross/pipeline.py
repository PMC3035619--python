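"""End-to-end seeded pipeline over the synthetic study.

simulate cross -> infer breed-of-origin coefficients -> mixed-model scans
-> q-values and peak calling -> local/distant classification -> eQTL/pQTL
co-localization.  Every stage derives its own child seed from the config's
master seed, and all outputs are deterministic TSV/JSON text files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, colocalize, io, significance
from .maps import LinkageMap
from .origin_prob import build_scan_grid, compute_ca_matrix, infer_marker_origins
from .scan import EQTLScanner, ModelSpec, fit_null_model, scan_transcript
from .synthetic_cross import (child_seed, make_truth, simulate_expression_study,
                              simulate_genotypes, simulate_pedigree,
                              simulate_phenotypes)

__all__ = ["run_pipeline"]


def run_pipeline(config: io.SimulationConfig, outdir, k_intermediate=None) -> dict:
    """Run the full synthetic analysis; write outputs under ``outdir``.

    Returns a dict of the in-memory results (pedigree, study, profiles,
    peaks, overlaps, ...).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    if k_intermediate is None:
        k_intermediate = cfg.k_intermediate

    lmap = LinkageMap.uniform(cfg.n_chromosomes, cfg.markers_per_chromosome,
                              cfg.marker_spacing_cM)
    ped = simulate_pedigree(cfg.n_f0_sires, cfg.n_f0_dams, cfg.n_f1_parents,
                            cfg.n_litters, cfg.f2_per_litter,
                            seed=child_seed(cfg.seed, "pedigree"))
    geno = simulate_genotypes(ped, lmap, cfg.informativeness, cfg.map_function,
                              seed=child_seed(cfg.seed, "genotypes"))
    truth = make_truth(lmap, cfg.n_probes, cfg.frac_eqtl, cfg.effect_size,
                       variances=cfg.variances, n_phenotypes=cfg.n_phenotypes,
                       seed=child_seed(cfg.seed, "truth"))
    study, truth, channel_map = simulate_expression_study(
        ped, geno, truth, seed=child_seed(cfg.seed, "expression"),
        lma_fraction=cfg.lma_litter_fraction)
    pheno = simulate_phenotypes(ped, geno, truth,
                                seed=child_seed(cfg.seed, "phenotypes"))

    grid = build_scan_grid(lmap, k_intermediate)
    inference = infer_marker_origins(ped, geno, lmap)
    ca = compute_ca_matrix(inference, grid, cfg.map_function)

    scanner = EQTLScanner(ca=ca)
    scanner.fit(study.expression, study.design)
    profiles = scanner.profiles_
    profiles = profiles.rename(columns={"trait": "trait"})
    profiles["q"] = significance.qvalues(profiles["p"].to_numpy())
    h2_map = scanner.summaries_.set_index("trait")["h2"]
    profiles["h2"] = profiles["trait"].map(h2_map)

    peaks = significance.call_peaks(profiles, significance.EXPLORATORY_P, grid, lmap)
    hotspots = significance.hotspot_counts(profiles, significance.EXPLORATORY_P,
                                           n_traits=cfg.n_probes)

    # probe positions: convert the simulated physical bp back to cM scale
    positions = truth.probe_positions.rename(columns={"chromosome": "chromosome"})
    positions = positions.assign(mismatches=0)
    filtered = annotate.filter_alignments(positions)
    classified = annotate.classify_peaks(peaks, filtered) if not peaks.empty else peaks

    # pQTL scans on the profiled samples (phenotype model: sex fixed,
    # litter random)
    pheno_design = study.design[["sample", "sex", "litter", "array",
                                 "dye", "growth_group"]].copy()
    pspec = ModelSpec(fixed=("sex",), random=("litter",))
    ppeaks_rows = []
    pprofiles = []
    for trait_name in truth.phenotypes["trait"]:
        yv = pheno.loc[list(pheno_design["sample"]), trait_name].to_numpy(float)
        prof = scan_transcript(yv, pheno_design, ca, spec=pspec, trait=trait_name)
        tab = prof.table.copy()
        tab.insert(0, "trait", trait_name)
        pprofiles.append(tab)
    pprofiles = pd.concat(pprofiles, ignore_index=True)
    ppeaks = significance.call_peaks(pprofiles, significance.EXPLORATORY_P, grid, lmap)

    e_regions = colocalize.regions_from_peaks(peaks, lmap) if not peaks.empty else []
    p_regions = (colocalize.regions_from_peaks(ppeaks, lmap, kind="pQTL")
                 if not ppeaks.empty else [])
    overlaps = colocalize.find_overlaps(e_regions, p_regions)
    groups = colocalize.merge_overlap_groups(overlaps, e_regions, p_regions)

    # ---- outputs ----
    cfg.to_yaml(outdir / "config.yaml")
    io.write_pedigree(ped, outdir / "pedigree.tsv")
    io.write_map(lmap, outdir / "map.tsv")
    io.write_genotypes(geno, outdir / "genotypes.tsv")
    io.write_design(study.design, outdir / "design.tsv")
    io.write_expression(study.expression, outdir / "expression.tsv")
    io.write_ca_matrix(ca, outdir / "ca_matrix.tsv")
    truth.to_json(outdir / "truth.json")
    grid.positions.to_csv(outdir / "scan_grid.tsv", sep="\t", index=False)
    profiles.to_csv(outdir / "scan_profiles.tsv", sep="\t", index=False,
                    float_format="%.6g")
    scanner.summaries_.to_csv(outdir / "scan_summaries.tsv", sep="\t",
                              index=False, float_format="%.6g")
    classified.to_csv(outdir / "peaks.tsv", sep="\t", index=False,
                      float_format="%.6g")
    hotspots.to_csv(outdir / "hotspots.tsv", sep="\t", index=False,
                    float_format="%.6g")
    pprofiles.to_csv(outdir / "pqtl_profiles.tsv", sep="\t", index=False,
                     float_format="%.6g")
    ppeaks.to_csv(outdir / "pqtl_peaks.tsv", sep="\t", index=False,
                  float_format="%.6g")
    overlaps.to_csv(outdir / "overlaps.tsv", sep="\t", index=False,
                    float_format="%.6g")
    groups.to_csv(outdir / "overlap_regions.tsv", sep="\t", index=False,
                  float_format="%.6g")
    annotate.write_positions_bed(filtered, outdir / "probe_positions.bed")

    return {
        "lmap": lmap, "pedigree": ped, "genotypes": geno, "truth": truth,
        "study": study, "channel_map": channel_map, "phenotypes": pheno,
        "grid": grid, "ca": ca, "profiles": profiles,
        "summaries": scanner.summaries_, "peaks": classified,
        "hotspots": hotspots, "pqtl_peaks": ppeaks, "overlaps": overlaps,
        "overlap_regions": groups,
    }
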