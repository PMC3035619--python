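"""Linkage maps and map functions.

Genetic distances are in centiMorgans (cM) throughout.  The two classical
map functions convert an inter-locus distance d into a recombination
fraction r: Haldane assumes crossovers form a Poisson process (no
interference), Kosambi allows positive interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMap",
    "haldane",
    "kosambi",
    "recombination_fraction",
    "MAP_FUNCTIONS",
]


def haldane(d_cM):
    """Haldane map function: r = (1 - exp(-2d)) / 2, d in Morgans."""
    d = np.asarray(d_cM, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def kosambi(d_cM):
    """Kosambi map function: r = tanh(2d) / 2, d in Morgans."""
    d = np.asarray(d_cM, dtype=float) / 100.0
    return 0.5 * np.tanh(2.0 * d)


MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}


def recombination_fraction(d_cM, map_function: str = "haldane"):
    try:
        return MAP_FUNCTIONS[map_function](d_cM)
    except KeyError:
        raise ValueError(
            f"unknown map function {map_function!r}; choose from {sorted(MAP_FUNCTIONS)}"
        ) from None


@dataclass
class LinkageMap:
    """An ordered set of markers on linkage groups.

    Parameters
    ----------
    markers : DataFrame with columns ``marker``, ``chromosome``, ``cM``
        Positions must be strictly increasing within a chromosome.
    chromosome_lengths : mapping chromosome -> length in cM.  If omitted,
        each chromosome extends to its last marker.
    """

    markers: pd.DataFrame
    chromosome_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"marker", "chromosome", "cM"}
        missing = req - set(self.markers.columns)
        if missing:
            raise ValueError(f"marker table missing columns {sorted(missing)}")
        self.markers = self.markers.reset_index(drop=True)
        for chrom, sub in self.markers.groupby("chromosome", sort=False):
            pos = sub["cM"].to_numpy(float)
            if np.any(pos < 0):
                raise ValueError(f"negative cM position on chromosome {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )
            length = self.chromosome_lengths.get(chrom)
            if length is None:
                self.chromosome_lengths[chrom] = float(pos[-1])
            elif length < pos[-1]:
                raise ValueError(
                    f"chromosome {chrom} length {length} cM is shorter than its "
                    f"last marker at {pos[-1]} cM"
                )
        if self.markers["marker"].duplicated().any():
            raise ValueError("duplicate marker ids")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chromosome"]))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def total_length_cM(self) -> float:
        return float(sum(self.chromosome_lengths[c] for c in self.chromosomes))

    def chromosome_markers(self, chrom) -> pd.DataFrame:
        sub = self.markers[self.markers["chromosome"] == chrom]
        if sub.empty:
            raise KeyError(f"no markers on chromosome {chrom!r}")
        return sub

    @classmethod
    def uniform(cls, n_chromosomes: int, markers_per_chromosome: int,
                spacing_cM: float = 20.0, prefix: str = "M") -> "LinkageMap":
        """A regular map: equal chromosomes with evenly spaced markers."""
        rows = []
        for c in range(1, n_chromosomes + 1):
            for m in range(markers_per_chromosome):
                rows.append((f"{prefix}{c}_{m + 1}", str(c), m * spacing_cM))
        df = pd.DataFrame(rows, columns=["marker", "chromosome", "cM"])
        lengths = {str(c): (markers_per_chromosome - 1) * spacing_cM
                   for c in range(1, n_chromosomes + 1)}
        return cls(df, lengths)
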