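"""Two-color microarray normalization and study assembly.

The normalization follows the standard two-channel workflow for spotted
arrays: per spot, M = log2(ch1/ch2) and A = (log2 ch1 + log2 ch2)/2; an
intensity-dependent loess trend of M on A is removed separately within each
print-tip block (location normalization), then block spreads are equalized
by MAD scaling while preserving the overall scale (scale normalization).
No background correction is applied.  Downstream linkage analysis consumes
per-sample single-channel log2 values reconstructed as A ± M/2, so that
array effects can be absorbed by a random Array term in the mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ExpressionStudy",
    "TwoColorNormalizer",
    "normalize_within_printtip",
    "scale_normalize",
    "assemble_study",
]

SPOT_COLUMNS = ("probe", "block", "ch1", "ch2")


@dataclass
class ExpressionStudy:
    """Normalized log2 expression aligned with the hybridization design.

    Attributes
    ----------
    expression : DataFrame, probes x samples, normalized log2 intensities.
    design : DataFrame with one row per sample and columns
        ``sample, array, dye, sex, litter, growth_group``.
    """

    expression: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        req = {"sample", "array", "dye", "sex", "litter", "growth_group"}
        missing = req - set(self.design.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        if self.design["sample"].duplicated().any():
            dup = self.design.loc[self.design["sample"].duplicated(), "sample"]
            raise ValueError(f"samples appear on more than one channel: {list(dup)}")
        extra = set(self.design["sample"]) - set(self.expression.columns)
        if extra:
            raise ValueError(f"design samples missing from expression: {sorted(extra)}")
        self.design = self.design.reset_index(drop=True)
        # keep expression columns in design order
        self.expression = self.expression[list(self.design["sample"])]

    @property
    def n_samples(self) -> int:
        return len(self.design)

    @property
    def n_probes(self) -> int:
        return len(self.expression)

    def dye_balance(self) -> pd.DataFrame:
        """Dye usage counts per growth group (balanced design: equal rows)."""
        return self.design.groupby(["growth_group", "dye"]).size().unstack(fill_value=0)


def _check_spots(spots: pd.DataFrame) -> pd.DataFrame:
    missing = set(SPOT_COLUMNS) - set(spots.columns)
    if missing:
        raise ValueError(f"spot table missing columns {sorted(missing)}")
    if (spots["ch1"] <= 0).any() or (spots["ch2"] <= 0).any():
        raise ValueError("non-positive intensities cannot enter normalization")
    return spots


def normalize_within_printtip(
    spots: pd.DataFrame,
    loess_span: float = 0.4,
    robust_iterations: int = 3,
    min_block_size: int = 10,
) -> pd.DataFrame:
    """Within-print-tip loess location normalization of one array scan.

    Parameters
    ----------
    spots : DataFrame with columns ``probe, block, ch1, ch2`` (median
        foreground intensities per channel; no background correction).
    loess_span : fraction of spots in the local regression window.
    robust_iterations : robustifying reweighting iterations.
    min_block_size : blocks smaller than this fall back to a whole-array
        fit (with a warning).

    Returns
    -------
    DataFrame with columns ``probe, block, A, M`` where M is the
    loess-detrended log-ratio.
    """
    spots = _check_spots(spots)
    ch1 = spots["ch1"].to_numpy(float)
    ch2 = spots["ch2"].to_numpy(float)
    M = np.log2(ch1) - np.log2(ch2)
    A = 0.5 * (np.log2(ch1) + np.log2(ch2))

    fitted = np.empty_like(M)
    blocks = spots["block"].to_numpy()
    small = []
    for blk in pd.unique(blocks):
        idx = np.flatnonzero(blocks == blk)
        if idx.size < min_block_size:
            small.append(blk)
            continue
        fitted[idx] = _loess_fit(M[idx], A[idx], loess_span, robust_iterations)
    if small:
        warnings.warn(
            f"print-tip blocks {small} below {min_block_size} spots; "
            "falling back to whole-array loess for them",
            stacklevel=2,
        )
        whole = _loess_fit(M, A, loess_span, robust_iterations)
        for blk in small:
            idx = np.flatnonzero(blocks == blk)
            fitted[idx] = whole[idx]

    return pd.DataFrame(
        {"probe": spots["probe"].to_numpy(), "block": blocks, "A": A, "M": M - fitted}
    )


def _loess_fit(M: np.ndarray, A: np.ndarray, span: float, iters: int) -> np.ndarray:
    if np.allclose(M, M[0]):
        # constant M: the trend is that constant
        return np.full_like(M, M[0])
    fit = lowess(M, A, frac=span, it=iters, return_sorted=False)
    return np.asarray(fit, float)


def scale_normalize(normalized: pd.DataFrame, by: str = "block") -> pd.DataFrame:
    """Equalize M spread across blocks, preserving the overall scale.

    Each block's M is divided by its MAD and multiplied by the geometric
    mean of all block MADs (Yang-style scale normalization).  Blocks with
    zero MAD are left unscaled with a warning.
    """
    out = normalized.copy()
    groups = out.groupby(by)["M"]
    mads = groups.apply(lambda m: float(np.median(np.abs(m - np.median(m)))))
    positive = mads[mads > 0]
    if positive.empty:
        warnings.warn("all blocks have zero MAD; scale normalization skipped", stacklevel=2)
        return out
    geo = float(np.exp(np.mean(np.log(positive))))
    zero = mads[mads == 0].index.tolist()
    if zero:
        warnings.warn(f"blocks {zero} have zero MAD; left unscaled", stacklevel=2)
    factors = out[by].map(lambda b: geo / mads[b] if mads[b] > 0 else 1.0)
    out["M"] = out["M"] * factors.to_numpy(float)
    return out


class TwoColorNormalizer(TransformerMixin, BaseEstimator):
    """Print-tip loess + scale normalization as a scikit-learn transformer.

    ``transform`` maps a spot-level table of one array scan (columns
    ``probe, block, ch1, ch2``) to normalized ``(probe, block, A, M)``
    records.  The transformer is stateless; ``fit`` only validates input.
    """

    def __init__(self, loess_span: float = 0.4, robust_iterations: int = 3,
                 min_block_size: int = 10, scale: bool = True):
        self.loess_span = loess_span
        self.robust_iterations = robust_iterations
        self.min_block_size = min_block_size
        self.scale = scale

    def fit(self, X: pd.DataFrame, y=None) -> "TwoColorNormalizer":
        _check_spots(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = normalize_within_printtip(
            X,
            loess_span=self.loess_span,
            robust_iterations=self.robust_iterations,
            min_block_size=self.min_block_size,
        )
        if self.scale:
            out = scale_normalize(out)
        return out


def assemble_study(
    normalized_by_array: dict,
    design: pd.DataFrame,
    channel_map: pd.DataFrame,
) -> ExpressionStudy:
    """Assemble per-sample log2 expression from normalized array scans.

    Parameters
    ----------
    normalized_by_array : mapping array id -> normalized spot table
        (``probe, block, A, M``) as produced by :class:`TwoColorNormalizer`.
    design : sample design table (sample, array, dye, sex, litter,
        growth_group).
    channel_map : DataFrame with columns ``array, channel, sample`` saying
        which sample was hybridized in channel 1 (numerator of M) and
        channel 2 of each array.

    The per-sample log2 value is reconstructed as A + M/2 for the channel-1
    sample and A - M/2 for the channel-2 sample, so the Array random effect
    of the linkage model absorbs the shared A component.
    """
    if design["sample"].duplicated().any():
        dup = sorted(design.loc[design["sample"].duplicated(), "sample"])
        raise ValueError(f"samples assigned to more than one channel: {dup}")
    columns = {}
    for _, row in channel_map.iterrows():
        arr, channel, sample = row["array"], int(row["channel"]), row["sample"]
        if arr not in normalized_by_array:
            raise ValueError(f"no normalized data for array {arr!r}")
        tab = normalized_by_array[arr]
        sign = 0.5 if channel == 1 else -0.5
        vals = tab["A"].to_numpy(float) + sign * tab["M"].to_numpy(float)
        columns[sample] = pd.Series(vals, index=tab["probe"].to_numpy())
    expr = pd.DataFrame(columns)
    missing = set(design["sample"]) - set(expr.columns)
    if missing:
        raise ValueError(f"design samples without expression data: {sorted(missing)}")
    study = ExpressionStudy(expr, design)
    balance = study.dye_balance()
    if balance.shape[1] == 2 and not (balance.iloc[:, 0] == balance.iloc[:, 1]).all():
        imbalance = (balance.iloc[:, 0] - balance.iloc[:, 1]).abs().sum()
        warnings.warn(
            f"dye assignment unbalanced across growth groups (total imbalance "
            f"{int(imbalance)} samples)",
            stacklevel=2,
        )
    return study
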