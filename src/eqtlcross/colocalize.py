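"""QTL region construction, overlap detection and overlap probability.

eQTL and pQTL peaks are extended into cM intervals (default 5 cM to each
side).  For two equal-length intervals whose centers are placed uniformly
and independently on a genome modeled as a single line of length G cM,
the probability that they overlap (center distance <= interval length L)
is

    P(overlap) = 2 L / G - (L / G)^2

and the p-value for observing a center distance as small as d is

    P(|u1 - u2| <= d) = 2 d / G - (d / G)^2 ,

which does not depend on the interval length.  Both closed forms are
verified against a Monte-Carlo null in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QTLRegion",
    "make_region",
    "find_overlaps",
    "merge_overlap_groups",
    "overlap_pvalue",
    "interval_overlap_probability",
    "mc_overlap_null",
    "DEFAULT_GENOME_CM",
    "DEFAULT_HALF_WIDTH_CM",
]

DEFAULT_GENOME_CM = 3000.0
DEFAULT_HALF_WIDTH_CM = 5.0


@dataclass(frozen=True)
class QTLRegion:
    trait: str
    kind: str  # "eQTL" or "pQTL"
    chromosome: str
    center_cM: float
    start_cM: float
    end_cM: float

    def __post_init__(self):
        if self.end_cM <= self.start_cM:
            raise ValueError(
                f"degenerate region for {self.trait}: [{self.start_cM}, {self.end_cM}]"
            )


def make_region(
    trait: str,
    chromosome,
    peak_cM: float,
    chromosome_length_cM: float,
    half_width_cM: float = DEFAULT_HALF_WIDTH_CM,
    kind: str = "eQTL",
) -> QTLRegion:
    """Peak +/- half_width, truncated at [0, chromosome length]."""
    if half_width_cM <= 0:
        raise ValueError("half_width_cM must be > 0")
    start = max(0.0, peak_cM - half_width_cM)
    end = min(float(chromosome_length_cM), peak_cM + half_width_cM)
    return QTLRegion(trait, kind, str(chromosome), float(peak_cM), start, end)


def regions_from_peaks(peaks: pd.DataFrame, lmap, half_width_cM=DEFAULT_HALF_WIDTH_CM,
                       kind: str = "eQTL") -> list:
    """Build regions from a peak table (trait, chromosome, peak_cM)."""
    return [
        make_region(row.trait, row.chromosome, row.peak_cM,
                    lmap.chromosome_lengths[row.chromosome], half_width_cM, kind)
        for row in peaks.itertuples()
    ]


def find_overlaps(
    eqtl_regions: list,
    pqtl_regions: list,
    genome_length_cM: float = DEFAULT_GENOME_CM,
) -> pd.DataFrame:
    """All same-chromosome intersecting (eQTL, pQTL) region pairs.

    Each pair carries the center distance, overlap span and the uniform-
    center overlap p-value.  Symmetric in its two inputs up to labels.
    """
    rows = []
    for e in eqtl_regions:
        for p in pqtl_regions:
            if e.chromosome != p.chromosome:
                continue
            span = min(e.end_cM, p.end_cM) - max(e.start_cM, p.start_cM)
            if span <= 0:
                continue
            dist = abs(e.center_cM - p.center_cM)
            rows.append({
                "eqtl_trait": e.trait, "pqtl_trait": p.trait,
                "chromosome": e.chromosome,
                "eqtl_cM": e.center_cM, "pqtl_cM": p.center_cM,
                "center_distance_cM": dist, "overlap_span_cM": span,
                "p_value": overlap_pvalue(dist, genome_length_cM),
            })
    return pd.DataFrame(rows, columns=[
        "eqtl_trait", "pqtl_trait", "chromosome", "eqtl_cM", "pqtl_cM",
        "center_distance_cM", "overlap_span_cM", "p_value"])


def merge_overlap_groups(overlaps: pd.DataFrame, eqtl_regions: list,
                         pqtl_regions: list) -> pd.DataFrame:
    """Group overlapping pairs into common genomic regions.

    Regions sharing any overlap (transitively, per chromosome) are merged
    into one reported interval; the group's p-value is the largest
    pairwise overlap p-value within the group.
    """
    if overlaps.empty:
        return pd.DataFrame(columns=[
            "chromosome", "start_cM", "end_cM", "eqtl_traits", "pqtl_traits",
            "n_overlaps", "p_value"])
    by_key = {(r.kind, r.trait, r.chromosome): r for r in eqtl_regions + pqtl_regions}
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        parent[find(a)] = find(b)

    for row in overlaps.itertuples():
        union(("eQTL", row.eqtl_trait, row.chromosome),
              ("pQTL", row.pqtl_trait, row.chromosome))
    groups = {}
    for row in overlaps.itertuples():
        root = find(("eQTL", row.eqtl_trait, row.chromosome))
        groups.setdefault(root, []).append(row)
    out = []
    for members in groups.values():
        keys = set()
        for row in members:
            keys.add(("eQTL", row.eqtl_trait, row.chromosome))
            keys.add(("pQTL", row.pqtl_trait, row.chromosome))
        regs = [by_key[k] for k in keys]
        out.append({
            "chromosome": members[0].chromosome,
            "start_cM": min(r.start_cM for r in regs),
            "end_cM": max(r.end_cM for r in regs),
            "eqtl_traits": ",".join(sorted({r.trait for r in regs if r.kind == "eQTL"})),
            "pqtl_traits": ",".join(sorted({r.trait for r in regs if r.kind == "pQTL"})),
            "n_overlaps": len(members),
            "p_value": max(row.p_value for row in members),
        })
    return (pd.DataFrame(out)
            .sort_values(["chromosome", "start_cM"])
            .reset_index(drop=True))


def overlap_pvalue(center_distance_cM: float,
                   genome_length_cM: float = DEFAULT_GENOME_CM) -> float:
    """P(two uniform interval centers fall within the observed distance)."""
    d, G = float(center_distance_cM), float(genome_length_cM)
    if d < 0:
        raise ValueError("distance must be >= 0")
    if d > G:
        raise ValueError(f"distance {d} exceeds genome length {G}")
    return float(np.clip(2 * d / G - (d / G) ** 2, 0.0, 1.0))


def interval_overlap_probability(interval_length_cM: float,
                                 genome_length_cM: float = DEFAULT_GENOME_CM) -> float:
    """P(two equal-length intervals with uniform centers overlap).

    Two intervals of length L overlap iff their centers are within L, so
    this is :func:`overlap_pvalue` evaluated at d = L.
    """
    L, G = float(interval_length_cM), float(genome_length_cM)
    if not 0 < L <= G:
        raise ValueError("interval length must be in (0, genome length]")
    return float(np.clip(2 * L / G - (L / G) ** 2, 0.0, 1.0))


def mc_overlap_null(genome_length_cM: float, n_draws: int, seed: int) -> np.ndarray:
    """Monte-Carlo null sample of center distances |u1 - u2|, u ~ U(0, G).

    Deterministic given the seed; the empirical CDF of the returned sample
    is the oracle for the closed forms above.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, genome_length_cM, size=(2, n_draws))
    return np.abs(u[0] - u[1])
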