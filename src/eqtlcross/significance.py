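"""Multiple-testing correction, linkage-peak calling, hotspot assessment.

Significance tiers mirror a two-stage genome-scan convention: an
exploratory nominal threshold (P < 1e-4) and a confirmatory threshold
(P < 3.5e-6, corresponding to FDR < 10% in the motivating study).
q-values are computed across all trait x position tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import LinkageMap
from .origin_prob import ScanGrid

__all__ = [
    "qvalues",
    "call_peaks",
    "hotspot_counts",
    "EXPLORATORY_P",
    "CONFIRMATORY_P",
]

EXPLORATORY_P = 1e-4
CONFIRMATORY_P = 3.5e-6


def qvalues(p, lambdas=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with smoother pi0 estimation.

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (m (1 - lambda))
    smoothed by a cubic polynomial over lambda in {0.05, ..., 0.95} and
    evaluated at the largest lambda.  When the input is short (< 100) or
    the estimate falls outside (0, 1], pi0 = 1 is used, which reduces to
    Benjamini-Hochberg.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.96, 0.05)
            lambdas = np.asarray(lambdas, float)
            pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_lam, 3)
            est = float(np.polyval(coef, lambdas.max()))
            pi0 = 1.0 if (est > 1 or est <= 0) else est
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    ranked = p[order]
    q_ord = pi0 * m * ranked / np.arange(1, m + 1)
    q_ord = np.minimum.accumulate(q_ord[::-1])[::-1]
    q[order] = np.minimum(q_ord, 1.0)
    return q


@dataclass
class PeakCall:
    """One collapsed linkage peak of one trait."""

    trait: str
    chromosome: str
    peak_cM: float
    peak_p: float
    peak_q: float
    left_marker: str
    right_marker: str
    a_hat: float
    breed_overexpressed: str
    h2: float
    run_size: int


def _parse_position(label: str):
    chrom, cm = str(label).rsplit("@", 1)
    return chrom, float(cm)


def call_peaks(
    profiles: pd.DataFrame,
    p_threshold: float,
    grid: ScanGrid,
    lmap: LinkageMap,
    q: dict | None = None,
) -> pd.DataFrame:
    """Collapse significant tests into linkage peaks.

    Per trait, contiguous runs of grid positions with p < threshold on one
    chromosome become a single peak at the run's minimum-p position (ties
    broken leftmost); a non-significant position or a chromosome boundary
    ends a run.  The positive additive effect weights Duroc origin, so
    a_hat > 0 at the peak means the Duroc allele is over-expressed.

    Parameters
    ----------
    profiles : long table with columns trait, position (``chrom@cM``),
        a_hat, p (grid order within trait), optionally q, h2.
    """
    peaks = []
    grid_order = {lbl: i for i, lbl in enumerate(
        f"{r.chromosome}@{r.cM:.1f}" for r in grid.positions.itertuples())}
    for trait, sub in profiles.groupby("trait", sort=False):
        sub = sub.sort_values("position", key=lambda s: s.map(grid_order))
        chroms = np.array([_parse_position(x)[0] for x in sub["position"]])
        cms = np.array([_parse_position(x)[1] for x in sub["position"]])
        sig = (sub["p"].to_numpy() < p_threshold)
        pvals = sub["p"].to_numpy()
        ahats = sub["a_hat"].to_numpy()
        qvals = sub["q"].to_numpy() if "q" in sub.columns else np.full(len(sub), np.nan)
        h2s = sub["h2"].to_numpy() if "h2" in sub.columns else np.full(len(sub), np.nan)

        i = 0
        while i < len(sub):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and sig[j + 1] and chroms[j + 1] == chroms[i]:
                j += 1
            run = slice(i, j + 1)
            k = i + int(np.argmin(pvals[run]))  # argmin takes the first = leftmost
            chrom, cm = chroms[k], cms[k]
            left, right = _flanking_markers(lmap, chrom, cm)
            peaks.append(PeakCall(
                trait=trait, chromosome=chrom, peak_cM=cm,
                peak_p=float(pvals[k]), peak_q=float(qvals[k]),
                left_marker=left, right_marker=right, a_hat=float(ahats[k]),
                breed_overexpressed="Duroc" if ahats[k] > 0 else "Pietrain",
                h2=float(h2s[k]), run_size=j - i + 1,
            ))
            i = j + 1
    cols = ["trait", "chromosome", "peak_cM", "peak_p", "peak_q",
            "left_marker", "right_marker", "a_hat", "breed_overexpressed",
            "h2", "run_size"]
    return pd.DataFrame([vars(pk) for pk in peaks], columns=cols)


def _flanking_markers(lmap: LinkageMap, chrom, cm: float):
    sub = lmap.chromosome_markers(chrom)
    pos = sub["cM"].to_numpy(float)
    ids = list(sub["marker"])
    iL = int(np.searchsorted(pos, cm, side="right")) - 1
    iR = int(np.searchsorted(pos, cm, side="left"))
    left = ids[max(iL, 0)]
    right = ids[min(iR, len(ids) - 1)]
    return left, right


def hotspot_counts(
    profiles: pd.DataFrame,
    alpha: float,
    n_traits: int,
) -> pd.DataFrame:
    """Count significant traits per grid position and flag hotspots.

    The null expectation at each position is n_traits * alpha (the
    expected number of false positives at any single putative QTL
    position); positions exceeding it are flagged as putative hotspots —
    a descriptive screen, not a corrected test.
    """
    if alpha < 0 or alpha > 1:
        raise ValueError("alpha must be in [0, 1]")
    sig = profiles[profiles["p"] < alpha]
    counts = sig.groupby("position", sort=False).size()
    all_pos = pd.unique(profiles["position"])
    counts = counts.reindex(all_pos, fill_value=0)
    expected = n_traits * alpha
    return pd.DataFrame({
        "position": counts.index,
        "n_significant": counts.to_numpy(int),
        "null_expectation": expected,
        "hotspot": counts.to_numpy() > expected,
    }).reset_index(drop=True)
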