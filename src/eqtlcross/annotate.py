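"""Probe genomic positioning and local/distant eQTL classification.

Probes are positioned from precomputed probe-to-genome alignment records
(e.g. BLAT output reduced to probe, chromosome, start, end, strand,
mismatches).  Alignments with more than ``max_mismatch`` mismatches are
dropped; probes that still align to more than one place are discarded as
ambiguous.  An eQTL is *local* when its linkage peak is on the same
chromosome as the probe's physical position, *distant* otherwise, and
*unpositioned* when the probe has no unique placement.  Genomic intervals
use BED conventions (0-based, half-open).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "filter_alignments",
    "classify_eqtl",
    "classify_peaks",
    "read_alignments",
    "write_positions_bed",
]

ALIGNMENT_COLUMNS = ("probe", "chromosome", "start", "end", "strand", "mismatches")


def filter_alignments(records: pd.DataFrame, max_mismatch: int = 3) -> pd.DataFrame:
    """Unique probe positions after the mismatch and multi-hit filters.

    Filtering is idempotent: applying it to its own output is a no-op.
    """
    missing = {"probe", "chromosome", "start", "mismatches"} - set(records.columns)
    if missing:
        raise ValueError(f"alignment table missing columns {sorted(missing)}")
    if (records["start"] < 0).any() or (records["mismatches"] < 0).any():
        raise ValueError("negative start or mismatch count")
    ok = records[records["mismatches"] <= max_mismatch]
    hit_counts = ok.groupby("probe")["chromosome"].transform("size")
    unique = ok[hit_counts == 1].copy()
    return unique.reset_index(drop=True)


def classify_eqtl(peak_chromosome, probe_chromosome) -> str:
    """local / distant / unpositioned for one peak."""
    if probe_chromosome is None or (isinstance(probe_chromosome, float)
                                    and np.isnan(probe_chromosome)):
        return "unpositioned"
    return "local" if str(peak_chromosome) == str(probe_chromosome) else "distant"


def classify_peaks(peaks: pd.DataFrame, positions: pd.DataFrame) -> pd.DataFrame:
    """Classify every peak against the filtered probe-position table.

    ``peaks`` needs columns trait (probe id) and chromosome; ``positions``
    is the output of :func:`filter_alignments`.
    """
    pos_by_probe = positions.set_index("probe")["chromosome"]
    out = peaks.copy()
    out["probe_chromosome"] = out["trait"].map(pos_by_probe)
    out["classification"] = [
        classify_eqtl(row.chromosome, row.probe_chromosome)
        for row in out.itertuples()
    ]
    return out


def read_alignments(path) -> pd.DataFrame:
    """Read an alignment TSV (probe, chromosome, start, end, strand,
    mismatches) or a BED file with the mismatch count in the score column."""
    df = pd.read_csv(path, sep="\t")
    if set(ALIGNMENT_COLUMNS) <= set(df.columns):
        return df
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 5:
        raise ValueError("need at least chrom,start,end,name,mismatches columns")
    df = df.iloc[:, :6]
    df.columns = ["chromosome", "start", "end", "probe", "mismatches", "strand"][: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df[list(ALIGNMENT_COLUMNS)]


def write_positions_bed(positions: pd.DataFrame, path) -> None:
    bed = positions[["chromosome", "start", "end", "probe"]].copy()
    bed["score"] = positions["mismatches"] if "mismatches" in positions else 0
    bed["strand"] = positions["strand"] if "strand" in positions else "+"
    bed.to_csv(path, sep="\t", header=False, index=False)
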