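"""Simulation of an F2 line-cross genetical-genomics experiment.

The simulated design mirrors a Duroc x Pietrain pig resource population:
purebred F0 sires (Duroc) and dams (Pietrain), an F1 generation, and F2
litters genotyped at microsatellite-like markers.  Expression profiling
uses selective phenotyping: the two extreme males and the two extreme
females of each litter (by a litter-specific selection criterion) are
hybridized pairwise on two-color arrays with balanced dyes.  Every
simulated quantity carries its ground truth, so downstream breed-of-origin
inference, mixed-model scans and peak calling can be validated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .maps import LinkageMap, recombination_fraction
from .preprocess import ExpressionStudy

__all__ = [
    "Pedigree",
    "GenotypeTable",
    "TruthTable",
    "StructuralError",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_expression_study",
    "simulate_phenotypes",
    "make_truth",
    "child_seed",
]

GROWTH_GROUPS = ("high_lma", "low_lma", "high_bf", "low_bf")
DYES = ("Cy3", "Cy5")


class StructuralError(ValueError):
    """The requested mating or selection structure is infeasible."""


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from one master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(abs(hash(stage)) % (2**31),))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Three-generation pedigree of a two-breed F2 cross.

    ``individuals`` has columns id, sire, dam, generation (F0/F1/F2),
    sex (M/F), breed (Duroc/Pietrain/cross), litter.
    """

    individuals: pd.DataFrame

    def __post_init__(self):
        df = self.individuals.reset_index(drop=True)
        if df["id"].duplicated().any():
            raise ValueError("duplicate individual ids")
        self.individuals = df
        self._by_id = df.set_index("id")
        self.validate()

    def validate(self):
        df = self._by_id
        f0 = df[df["generation"] == "F0"]
        if not (f0["sire"].isna().all() and f0["dam"].isna().all()):
            raise ValueError("F0 individuals must have no parents")
        for gen, expected_breeds in (("F1", {"Duroc"}), ("F2", {"cross"})):
            sub = df[df["generation"] == gen]
            for iid, row in sub.iterrows():
                sire, dam = row["sire"], row["dam"]
                if pd.isna(sire) or pd.isna(dam):
                    raise ValueError(f"{gen} individual {iid} lacks parents")
                if gen == "F1":
                    if df.loc[sire, "breed"] != "Duroc" or df.loc[dam, "breed"] != "Pietrain":
                        raise ValueError(
                            f"F1 {iid} must have a Duroc sire and Pietrain dam"
                        )
                else:
                    if df.loc[sire, "generation"] != "F1" or df.loc[dam, "generation"] != "F1":
                        raise ValueError(f"F2 {iid} must have F1 parents")

    def generation(self, gen: str) -> pd.DataFrame:
        return self.individuals[self.individuals["generation"] == gen]

    @property
    def f2_ids(self) -> list:
        return list(self.generation("F2")["id"])

    def parents_of(self, iid) -> tuple:
        row = self._by_id.loc[iid]
        return row["sire"], row["dam"]

    def sex_of(self, iid) -> str:
        return self._by_id.loc[iid, "sex"]

    def litter_of(self, iid):
        return self._by_id.loc[iid, "litter"]

    def litters(self) -> dict:
        f2 = self.generation("F2")
        return {lit: list(sub["id"]) for lit, sub in f2.groupby("litter", sort=False)}


def simulate_pedigree(
    n_f0_sires: int,
    n_f0_dams: int,
    n_f1_parents: int,
    n_litters: int,
    f2_per_litter: int,
    seed: int,
    f1_male_fraction: float = 6 / 56,
) -> Pedigree:
    """Simulate the three-generation mating structure.

    F1 sexes follow ``f1_male_fraction`` (default mirrors retaining 6 males
    and 50 females out of 56 F1); at least one male and one female are
    always produced.  F2 sexes are balanced within litter so that two
    extreme males and two extreme females can later be selected per litter.
    """
    for name, v in (("n_f0_sires", n_f0_sires), ("n_f0_dams", n_f0_dams),
                    ("n_f1_parents", n_f1_parents), ("n_litters", n_litters),
                    ("f2_per_litter", f2_per_litter)):
        if v < 1:
            raise StructuralError(f"{name} must be >= 1 (got {v})")
    if n_f1_parents < 2:
        raise StructuralError("need at least 2 F1 parents (one male, one female)")
    rng = np.random.default_rng(seed)
    rows = []
    sires = [f"F0S{i + 1}" for i in range(n_f0_sires)]
    dams = [f"F0D{i + 1}" for i in range(n_f0_dams)]
    for s in sires:
        rows.append((s, None, None, "F0", "M", "Duroc", None))
    for d in dams:
        rows.append((d, None, None, "F0", "F", "Pietrain", None))

    n_f1_males = int(np.clip(round(n_f1_parents * f1_male_fraction), 1, n_f1_parents - 1))
    f1_sexes = np.array(["M"] * n_f1_males + ["F"] * (n_f1_parents - n_f1_males))
    rng.shuffle(f1_sexes)
    f1_ids = [f"F1_{i + 1}" for i in range(n_f1_parents)]
    for iid, sex in zip(f1_ids, f1_sexes):
        rows.append((iid, rng.choice(sires), rng.choice(dams), "F1", sex, "cross", None))
    f1_males = [i for i, s in zip(f1_ids, f1_sexes) if s == "M"]
    f1_females = [i for i, s in zip(f1_ids, f1_sexes) if s == "F"]

    # each F1 dam is used for at most one litter while any remain unused
    dam_pool = list(f1_females)
    rng.shuffle(dam_pool)
    f2_counter = 0
    for lit_idx in range(n_litters):
        litter = f"L{lit_idx + 1:03d}"
        sire = f1_males[int(rng.integers(len(f1_males)))]
        if dam_pool:
            dam = dam_pool.pop()
        else:
            dam = f1_females[int(rng.integers(len(f1_females)))]
        n_m = f2_per_litter // 2
        sexes = np.array(["M"] * n_m + ["F"] * (f2_per_litter - n_m))
        rng.shuffle(sexes)
        for sex in sexes:
            f2_counter += 1
            rows.append((f"F2_{f2_counter:04d}", sire, dam, "F2", sex, "cross", litter))

    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "sex", "breed", "litter"])
    return Pedigree(df)


# ---------------------------------------------------------------------------
# Gametes and genotypes
# ---------------------------------------------------------------------------

@dataclass
class Transmission:
    """Which parental homolog (0 or 1) a gamete carries along a chromosome.

    Piecewise constant: the state starts at ``start_state`` at 0 cM and
    flips at each crossover breakpoint.
    """

    start_state: int
    breakpoints: np.ndarray  # sorted cM positions

    def state_at(self, pos_cM) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos_cM, float))
        flips = np.searchsorted(self.breakpoints, pos, side="right")
        out = (self.start_state + flips) % 2
        return out if np.ndim(pos_cM) else int(out[0])


def _simulate_transmission(rng, grid: np.ndarray, rfracs: np.ndarray) -> Transmission:
    """Markov transmission over a position grid; at most one uniformly
    placed crossover per interval."""
    start = int(rng.integers(2))
    switches = rng.random(len(rfracs)) < rfracs
    bps = [float(rng.uniform(grid[i], grid[i + 1])) for i in np.flatnonzero(switches)]
    return Transmission(start, np.asarray(bps, float))


@dataclass
class GenotypeTable:
    """Observed marker genotypes plus (for simulations) latent breed origin.

    ``ordered`` maps individual id -> (n_markers, 2) allele array with the
    paternal haplotype in column 0.  For F2s the paternal/maternal homolog
    breed-origin functions are stored per chromosome as transmissions over
    the F1 parents' homologs (F1 homolog 0 is always the Duroc-origin one).
    """

    lmap: LinkageMap
    ordered: dict
    informative_markers: np.ndarray
    f2_transmissions: dict = field(default_factory=dict)

    @property
    def marker_ids(self) -> list:
        return list(self.lmap.markers["marker"])

    def alleles(self, iid, marker_index: int) -> tuple:
        pair = self.ordered[iid][marker_index]
        return int(pair[0]), int(pair[1])

    def observed(self) -> pd.DataFrame:
        """Unordered genotype table, alleles as 'a/b' with a <= b."""
        data = {}
        for iid, arr in self.ordered.items():
            lo = np.minimum(arr[:, 0], arr[:, 1])
            hi = np.maximum(arr[:, 0], arr[:, 1])
            data[iid] = [f"{a}/{b}" for a, b in zip(lo, hi)]
        return pd.DataFrame(data, index=self.marker_ids).T

    def origin_pair_at(self, f2_id, chrom, pos_cM) -> tuple:
        """True (paternal, maternal) breed origin of an F2 at any position."""
        t_pat, t_mat = self.f2_transmissions[f2_id][chrom]
        code = {0: "D", 1: "P"}
        return code[t_pat.state_at(pos_cM)], code[t_mat.state_at(pos_cM)]

    def origin_code_at(self, f2_id, chrom, pos_cM) -> int:
        """Additive code at a position: DD=+1, DP=0, PP=-1."""
        pat, mat = self.origin_pair_at(f2_id, chrom, pos_cM)
        return (pat == "D") + (mat == "D") - 1

    def origin_codes(self, f2_ids, chrom, pos_cM) -> np.ndarray:
        return np.array([self.origin_code_at(i, chrom, pos_cM) for i in f2_ids])


def simulate_genotypes(
    pedigree: Pedigree,
    lmap: LinkageMap,
    informativeness: float = 1.0,
    map_function: str = "haldane",
    seed: int = 0,
) -> GenotypeTable:
    """Drop genotypes through the pedigree with recombination.

    Each marker is breed-informative with probability ``informativeness``:
    informative markers have disjoint Duroc {1,2} and Pietrain {3,4}
    founder allele pools, uninformative markers share the pool {1,2}.
    Gamete transmission follows a Markov chain over marker intervals with
    the chosen map function's recombination fraction per interval and at
    most one crossover per interval.
    """
    if not 0 <= informativeness <= 1:
        raise ValueError("informativeness must be in [0, 1]")
    if lmap.n_markers == 0:
        raise ValueError("empty linkage map")
    rng = np.random.default_rng(seed)
    markers = lmap.markers
    n_mark = len(markers)
    informative = rng.random(n_mark) < informativeness

    # per-chromosome simulation grids: 0, markers..., chromosome length
    chrom_grid = {}
    chrom_idx = {}
    for chrom in lmap.chromosomes:
        sub = lmap.chromosome_markers(chrom)
        pos = sub["cM"].to_numpy(float)
        grid = np.unique(np.concatenate([[0.0], pos, [lmap.chromosome_lengths[chrom]]]))
        rf = recombination_fraction(np.diff(grid), map_function)
        chrom_grid[chrom] = (grid, np.atleast_1d(rf))
        chrom_idx[chrom] = (sub.index.to_numpy(), pos)

    def gamete_from(parent_ordered: dict):
        """Simulate one gamete: per-chromosome transmissions + allele vector."""
        alleles = np.empty(n_mark, dtype=int)
        trans = {}
        for chrom in lmap.chromosomes:
            grid, rf = chrom_grid[chrom]
            t = _simulate_transmission(rng, grid, rf)
            trans[chrom] = t
            idx, pos = chrom_idx[chrom]
            states = t.state_at(pos)
            alleles[idx] = parent_ordered[idx, states]
        return alleles, trans

    ordered = {}
    # founders: draw ordered alleles from breed pools
    for _, row in pedigree.generation("F0").iterrows():
        if row["breed"] == "Pietrain":
            pool_lo = np.where(informative, 3, 1)
        else:
            pool_lo = np.ones(n_mark, dtype=int)
        draws = rng.integers(0, 2, size=(n_mark, 2))
        ordered[row["id"]] = pool_lo[:, None] + draws

    for _, row in pedigree.generation("F1").iterrows():
        pat, _ = gamete_from(ordered[row["sire"]])   # Duroc-origin homolog
        mat, _ = gamete_from(ordered[row["dam"]])    # Pietrain-origin homolog
        ordered[row["id"]] = np.column_stack([pat, mat])

    f2_trans = {}
    for _, row in pedigree.generation("F2").iterrows():
        pat, t_pat = gamete_from(ordered[row["sire"]])
        mat, t_mat = gamete_from(ordered[row["dam"]])
        ordered[row["id"]] = np.column_stack([pat, mat])
        f2_trans[row["id"]] = {c: (t_pat[c], t_mat[c]) for c in lmap.chromosomes}

    return GenotypeTable(lmap, ordered, informative, f2_trans)


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth of the simulated study.

    transcripts: one row per probe with eQTL position (or NaN), additive
    effect ``a``, variance components and fixed-effect coefficients.
    probe_positions: simulated physical probe locations (BED-like).
    phenotypes: pQTL truth for organismal traits.
    """

    transcripts: pd.DataFrame
    probe_positions: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self):
        for col in ("sigma2_array", "sigma2_litter", "sigma2_e"):
            if (self.transcripts[col] < 0).any():
                raise ValueError(f"negative variance component in column {col}")
        eff = self.transcripts[["a", "mu", "b_dye", "b_sex"]].to_numpy(float)
        if not np.isfinite(eff).all():
            raise ValueError("non-finite effects in truth table")

    def to_json(self, path):
        payload = {
            "transcripts": self.transcripts.to_dict(orient="list"),
            "probe_positions": self.probe_positions.to_dict(orient="list"),
            "phenotypes": self.phenotypes.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pd.DataFrame(payload["transcripts"]),
            pd.DataFrame(payload["probe_positions"]),
            pd.DataFrame(payload["phenotypes"]),
        )


#: log2-scale defaults for expression variance components.  Typical
#: two-color microarray studies show technical array variation and litter
#: (rearing-environment) variation that are small relative to biological
#: residual noise; see docs/methods.md.
DEFAULT_VARIANCES = {"sigma2_array": 0.05, "sigma2_litter": 0.05, "sigma2_e": 1.0}

BP_PER_CM = 1_000_000  # descriptive physical scale used for probe positions


def make_truth(
    lmap: LinkageMap,
    n_probes: int,
    frac_eqtl: float = 0.1,
    effect_size: float = 0.5,
    frac_local: float = 0.65,
    variances: Optional[dict] = None,
    n_phenotypes: int = 3,
    phenotype_effect: float = 0.5,
    pqtl_at_eqtl_fraction: float = 0.5,
    seed: int = 0,
) -> TruthTable:
    """Draw a truth table: which probes carry eQTL, where, how strong.

    eQTL are placed at marker positions (where breed-of-origin information
    is sharpest); a fraction ``frac_local`` of eQTL probes lie physically
    at their eQTL (local), the rest on another chromosome (distant).
    """
    rng = np.random.default_rng(seed)
    var = dict(DEFAULT_VARIANCES)
    if variances:
        var.update(variances)
    markers = lmap.markers
    n_eqtl = int(round(n_probes * frac_eqtl))
    has_eqtl = np.zeros(n_probes, bool)
    has_eqtl[:n_eqtl] = True
    rng.shuffle(has_eqtl)

    probe_ids = [f"probe_{i + 1:05d}" for i in range(n_probes)]
    chroms = lmap.chromosomes
    rows, pos_rows = [], []
    for pid, has in zip(probe_ids, has_eqtl):
        if has:
            mrow = markers.iloc[int(rng.integers(len(markers)))]
            eq_chrom, eq_cm = mrow["chromosome"], float(mrow["cM"])
            a = effect_size * (1 if rng.random() < 0.5 else -1)
            if rng.random() < frac_local:
                p_chrom, p_cm = eq_chrom, eq_cm + rng.uniform(-2, 2)
            else:
                others = [c for c in chroms if c != eq_chrom] or chroms
                p_chrom = others[int(rng.integers(len(others)))]
                p_cm = rng.uniform(0, lmap.chromosome_lengths[p_chrom])
        else:
            eq_chrom, eq_cm, a = None, np.nan, 0.0
            p_chrom = chroms[int(rng.integers(len(chroms)))]
            p_cm = rng.uniform(0, lmap.chromosome_lengths[p_chrom])
        rows.append((pid, eq_chrom, eq_cm, a,
                     var["sigma2_array"], var["sigma2_litter"], var["sigma2_e"],
                     8.0, 0.1, 0.05, 0.0, 0.0, 0.0, 0.0))
        start = max(0, int(round(p_cm * BP_PER_CM)))
        pos_rows.append((pid, p_chrom, start, start + 70, "+"))

    transcripts = pd.DataFrame(rows, columns=[
        "probe", "eqtl_chrom", "eqtl_cM", "a",
        "sigma2_array", "sigma2_litter", "sigma2_e",
        "mu", "b_dye", "b_sex", "b_high_lma", "b_low_lma", "b_high_bf", "b_low_bf",
    ])
    probe_positions = pd.DataFrame(
        pos_rows, columns=["probe", "chromosome", "start", "end", "strand"])

    # phenotype QTL: a fraction sit at eQTL positions, emulating shared
    # genetic control of expression and organismal traits
    eqtl_sites = transcripts.dropna(subset=["eqtl_cM"])
    ph_rows = []
    for k in range(n_phenotypes):
        if len(eqtl_sites) and rng.random() < pqtl_at_eqtl_fraction:
            srow = eqtl_sites.iloc[int(rng.integers(len(eqtl_sites)))]
            chrom, cm = srow["eqtl_chrom"], float(srow["eqtl_cM"])
        else:
            mrow = markers.iloc[int(rng.integers(len(markers)))]
            chrom, cm = mrow["chromosome"], float(mrow["cM"])
        ph_rows.append((f"trait_{k + 1}", chrom, cm,
                        phenotype_effect, var["sigma2_litter"], 1.0))
    phenotypes = pd.DataFrame(
        ph_rows, columns=["trait", "pqtl_chrom", "pqtl_cM", "effect",
                          "sigma2_litter", "sigma2_e"])
    return TruthTable(transcripts, probe_positions, phenotypes)


# ---------------------------------------------------------------------------
# Expression study simulation
# ---------------------------------------------------------------------------

def _select_extremes(pedigree: Pedigree, rng, lma_fraction: float):
    """Selective phenotyping: two extreme males and females per litter.

    Returns the design table (one row per selected F2) and array pairings.
    """
    litters = pedigree.litters()
    litter_ids = list(litters)
    n_lma = int(round(len(litter_ids) * lma_fraction))
    design_rows, channel_rows = [], []
    array_counter = 0
    for lit_idx, lit in enumerate(litter_ids):
        members = litters[lit]
        trait = {iid: rng.normal() for iid in members}
        males = sorted((i for i in members if pedigree.sex_of(i) == "M"),
                       key=lambda i: trait[i])
        females = sorted((i for i in members if pedigree.sex_of(i) == "F"),
                         key=lambda i: trait[i])
        if len(males) < 2 or len(females) < 2:
            raise StructuralError(
                f"litter {lit} has {len(males)} males / {len(females)} females; "
                "need at least 2 of each for extreme selection"
            )
        crit = "lma" if lit_idx < n_lma else "bf"
        picks = {
            "high_M": males[-1], "low_M": males[0],
            "high_F": females[-1], "low_F": females[0],
        }
        # within a litter, the high male and the low female share a dye and
        # the dye pairs alternate across litters so each dye is used equally
        # in each phenotype group across the experiment
        dye_x, dye_y = (DYES[0], DYES[1]) if lit_idx % 2 == 0 else (DYES[1], DYES[0])
        dye_of = {"high_M": dye_x, "low_M": dye_y, "high_F": dye_y, "low_F": dye_x}
        for sex_label, pair in (("M", ("high_M", "low_M")), ("F", ("high_F", "low_F"))):
            array_counter += 1
            arr = f"A{array_counter:04d}"
            for ch, key in enumerate(pair, start=1):
                iid = picks[key]
                extreme = key.split("_")[0]
                design_rows.append({
                    "sample": iid, "array": arr, "dye": dye_of[key],
                    "sex": sex_label, "litter": lit,
                    "growth_group": f"{extreme}_{crit}",
                    "extreme": extreme, "selection_trait": trait[iid],
                })
                channel_rows.append({"array": arr, "channel": ch, "sample": iid})
    design = pd.DataFrame(design_rows)
    channel_map = pd.DataFrame(channel_rows)
    return design, channel_map


def simulate_expression_study(
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    truth: TruthTable,
    seed: int = 0,
    lma_fraction: float = 24 / 44,
):
    """Generate normalized log2 expression for the selective-phenotyping design.

    The model per probe and sample is
    ``y = mu + Dye + Sex + growth_group + c_a * a + Array + Litter + e``
    with ``c_a`` the true breed-origin code (+1 Duroc homozygous, 0
    heterozygous, -1 Pietrain homozygous) at the probe's true eQTL
    position, and Array/Litter/e independent normals with the truth's
    variance components.

    Returns (ExpressionStudy, TruthTable, channel_map).
    """
    rng = np.random.default_rng(seed)
    design, channel_map = _select_extremes(pedigree, rng, lma_fraction)
    samples = list(design["sample"])
    n = len(samples)

    tr = truth.transcripts
    dye_ind = (design["dye"] == "Cy5").to_numpy(float)
    sex_ind = (design["sex"] == "M").to_numpy(float)
    gg = design["growth_group"].to_numpy()
    arrays = design["array"].to_numpy()
    litters = design["litter"].to_numpy()
    uniq_arrays = pd.unique(arrays)
    uniq_litters = pd.unique(litters)
    arr_idx = pd.Series(range(len(uniq_arrays)), index=uniq_arrays)[arrays].to_numpy()
    lit_idx = pd.Series(range(len(uniq_litters)), index=uniq_litters)[litters].to_numpy()

    gg_cols = {g: (gg == g).astype(float) for g in GROWTH_GROUPS}
    expr = np.empty((len(tr), n))
    for k, row in enumerate(tr.itertuples(index=False)):
        y = (row.mu + row.b_dye * dye_ind + row.b_sex * sex_ind
             + row.b_high_lma * gg_cols["high_lma"] + row.b_low_lma * gg_cols["low_lma"]
             + row.b_high_bf * gg_cols["high_bf"] + row.b_low_bf * gg_cols["low_bf"])
        if not pd.isna(row.eqtl_cM) and row.a != 0:
            codes = genotypes.origin_codes(samples, row.eqtl_chrom, float(row.eqtl_cM))
            y = y + row.a * codes
        if row.sigma2_array > 0:
            y = y + (np.sqrt(row.sigma2_array) * rng.normal(size=len(uniq_arrays)))[arr_idx]
        if row.sigma2_litter > 0:
            y = y + (np.sqrt(row.sigma2_litter) * rng.normal(size=len(uniq_litters)))[lit_idx]
        if row.sigma2_e > 0:
            y = y + np.sqrt(row.sigma2_e) * rng.normal(size=n)
        expr[k] = y

    expression = pd.DataFrame(expr, index=list(tr["probe"]), columns=samples)
    study = ExpressionStudy(expression, design)
    return study, truth, channel_map


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    truth: TruthTable,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate organismal phenotypes with pQTL for all F2 individuals."""
    rng = np.random.default_rng(seed)
    f2 = pedigree.generation("F2")
    ids = list(f2["id"])
    litters = f2["litter"].to_numpy()
    uniq_lit = pd.unique(litters)
    lit_idx = pd.Series(range(len(uniq_lit)), index=uniq_lit)[litters].to_numpy()
    out = {}
    for row in truth.phenotypes.itertuples(index=False):
        codes = genotypes.origin_codes(ids, row.pqtl_chrom, float(row.pqtl_cM))
        y = (row.effect * codes
             + (np.sqrt(row.sigma2_litter) * rng.normal(size=len(uniq_lit)))[lit_idx]
             + np.sqrt(row.sigma2_e) * rng.normal(size=len(ids)))
        out[row.trait] = y
    pheno = pd.DataFrame(out, index=ids)
    pheno.insert(0, "sex", f2["sex"].to_numpy())
    pheno.insert(1, "litter", litters)
    return pheno
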