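"""Tab-delimited file IO and the YAML simulation config.

All artifacts are plain text: pedigree/map/genotype/design/expression
TSVs, probe-position BED, truth JSON, and a YAML config holding every
count, variance, effect size and the master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .maps import LinkageMap
from .synthetic_cross import GenotypeTable, Pedigree

__all__ = [
    "SimulationConfig",
    "write_pedigree", "read_pedigree",
    "write_map", "read_map",
    "write_genotypes",
    "write_design",
    "write_expression", "read_expression",
    "write_ca_matrix", "read_ca_matrix",
]


@dataclass
class SimulationConfig:
    """Every knob of the synthetic study, serializable to YAML.

    Defaults reproduce the motivating experimental design: 4 Duroc F0
    sires x 16 Pietrain F0 dams, 56 F1, 44 litters with 4 profiled F2
    each (176 samples), a multi-chromosome microsatellite-like map, and
    log2-scale expression variance components.
    """

    n_f0_sires: int = 4
    n_f0_dams: int = 16
    n_f1_parents: int = 56
    n_litters: int = 44
    f2_per_litter: int = 4
    n_chromosomes: int = 19
    markers_per_chromosome: int = 7
    marker_spacing_cM: float = 24.0
    informativeness: float = 1.0
    map_function: str = "haldane"
    k_intermediate: int = 11
    n_probes: int = 500
    frac_eqtl: float = 0.1
    effect_size: float = 0.5
    lma_litter_fraction: float = 24 / 44
    variances: dict = field(default_factory=lambda: {
        "sigma2_array": 0.05, "sigma2_litter": 0.05, "sigma2_e": 1.0})
    n_phenotypes: int = 3
    seed: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.individuals.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str,
                                            "litter": str})
    return Pedigree(df)


def write_map(lmap: LinkageMap, path) -> None:
    df = lmap.markers.copy()
    df["chromosome_length_cM"] = df["chromosome"].map(lmap.chromosome_lengths)
    df.to_csv(path, sep="\t", index=False)


def read_map(path) -> LinkageMap:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    lengths = {}
    if "chromosome_length_cM" in df.columns:
        lengths = dict(df.groupby("chromosome")["chromosome_length_cM"].first())
        df = df.drop(columns=["chromosome_length_cM"])
    return LinkageMap(df, lengths)


def write_genotypes(genotypes: GenotypeTable, path) -> None:
    obs = genotypes.observed()
    obs.index.name = "individual"
    obs.to_csv(path, sep="\t")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_expression(expression: pd.DataFrame, path, float_format="%.6f") -> None:
    out = expression.copy()
    out.index.name = "probe"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe")


def write_ca_matrix(ca: pd.DataFrame, path, float_format="%.6f") -> None:
    out = ca.copy()
    out.index.name = "individual"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_ca_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual")
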