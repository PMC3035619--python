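"""Per-transcript linear mixed-model eQTL scan.

Model per transcript (and per phenotype for pQTL scans):

    Y = mu + Dye + Sex + growth_group + c_a * a + Array + Litter + e

with Dye/Sex/growth_group fixed, Array and Litter independent random
effects and e residual.  Variance components are estimated once per
transcript by REML under the null model (no c_a term) and then held fixed
while the additive effect a is tested by generalized least squares at
every scan position — the computationally tractable implementation of the
line-cross regression: one REML fit plus thousands of cheap GLS t-tests
per transcript instead of millions of mixed-model fits.

When each array's channels fall inside a single litter and all arrays in
a litter carry equally many samples (the paired selective-phenotyping
design), the covariance I + g_a Z_a Z_a' + g_l Z_l Z_l' has a shared
eigenbasis independent of the variance ratios; REML evaluations then cost
O(n) after a one-time rotation.  A generic Cholesky path covers every
other design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "NullModelFit",
    "ScanProfile",
    "ConvergenceError",
    "ConfoundingError",
    "build_design_matrix",
    "fit_null_model",
    "scan_transcript",
    "variance_explained",
    "EQTLScanner",
]

_ALIAS_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ConfoundingError(ValueError):
    """A fixed effect is aliased with a random grouping factor."""


@dataclass
class ModelSpec:
    """Which design columns enter the model and how."""

    fixed: Sequence[str] = ("dye", "sex", "growth_group")
    random: Sequence[str] = ("array", "litter")


def build_design_matrix(design: pd.DataFrame, fixed: Sequence[str]):
    """Intercept + treatment-coded dummies; aliased columns dropped
    first-kept (sequential Gram-Schmidt test) and reported."""
    n = len(design)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in fixed:
        levels = pd.unique(design[term])
        for lev in levels[1:]:
            cols.append((design[term] == lev).to_numpy(float))
            names.append(f"{term}[{lev}]")
    X = np.column_stack(cols)
    keep, dropped = [], []
    basis = np.zeros((n, 0))
    for j in range(X.shape[1]):
        v = X[:, j]
        resid = v - basis @ (basis.T @ v)
        nrm = np.linalg.norm(resid)
        if nrm > _ALIAS_TOL * max(1.0, np.linalg.norm(v)):
            keep.append(j)
            basis = np.column_stack([basis, resid / nrm])
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}", stacklevel=2)
    return X[:, keep], [names[j] for j in keep], dropped


def _check_confounding(design: pd.DataFrame, fixed: Sequence[str], random: Sequence[str]):
    """Reject fixed terms whose sample partition equals a random factor's.

    A fixed effect that merely stays constant within random groups (e.g.
    sex within same-sex arrays) is estimable from between-group contrasts
    and allowed; a fixed factor that reproduces the random factor's
    partition exactly makes the variance component unidentifiable.
    """
    for factor in random:
        f_codes = pd.factorize(design[factor])[0]
        for term in fixed:
            t_codes = pd.factorize(design[term])[0]
            pairs = set(zip(f_codes, t_codes))
            if (len(pairs) == len(set(f_codes)) == len(set(t_codes))
                    and len(set(t_codes)) > 1):
                raise ConfoundingError(
                    f"fixed effect {term!r} and random factor {factor!r} "
                    "partition the samples identically (aliased)"
                )


# ---------------------------------------------------------------------------
# Covariance structure
# ---------------------------------------------------------------------------

@dataclass
class _Structure:
    """Rotation/Cholesky machinery for W = I + sum_k g_k Z_k Z_k'."""

    Z: list                       # incidence matrices, one per random factor
    names: list
    Q: Optional[np.ndarray]       # shared eigenbasis (fast path) or None
    coefs: Optional[np.ndarray]   # (n, n_factors) eigenvalue multipliers

    def eigvals(self, gammas) -> np.ndarray:
        return 1.0 + self.coefs @ np.asarray(gammas)

    def W(self, gammas) -> np.ndarray:
        n = self.Z[0].shape[0]
        W = np.eye(n)
        for g, Z in zip(gammas, self.Z):
            if g > 0:
                W += g * (Z @ Z.T)
        return W


def _incidence(design: pd.DataFrame, factor: str) -> np.ndarray:
    codes, _ = pd.factorize(design[factor])
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _build_structure(design: pd.DataFrame, random: Sequence[str]) -> _Structure:
    Z = [_incidence(design, f) for f in random]
    names = list(random)
    Q = coefs = None
    if names == ["array", "litter"]:
        Q, coefs = _nested_eigenbasis(design)
    elif names == ["litter"]:
        Q, coefs = _single_factor_eigenbasis(design, "litter")
    elif names == ["array"]:
        Q, coefs = _single_factor_eigenbasis(design, "array")
    return _Structure(Z, names, Q, coefs)


def _single_factor_eigenbasis(design: pd.DataFrame, factor: str):
    n = len(design)
    Q = np.zeros((n, n))
    coefs = np.zeros((n, 1))
    col = 0
    groups = design.groupby(factor, sort=False).indices
    for idx in groups.values():
        idx = np.asarray(idx)
        m = len(idx)
        basis = _helmert(m)
        Q[idx, col] = basis[:, 0]
        coefs[col, 0] = m
        for j in range(1, m):
            Q[idx, col + j] = basis[:, j]
        col += m
    return Q, coefs


def _helmert(m: int) -> np.ndarray:
    """Orthonormal basis of R^m whose first vector is the normalized mean."""
    B = np.zeros((m, m))
    B[:, 0] = 1.0 / np.sqrt(m)
    for j in range(1, m):
        B[:j, j] = 1.0
        B[j, j] = -j
        B[:, j] /= np.sqrt(j * (j + 1))
    return B


def _nested_eigenbasis(design: pd.DataFrame):
    """Shared eigenbasis for array-within-litter designs, or None."""
    n = len(design)
    arrays = design["array"].to_numpy()
    litters = design["litter"].to_numpy()
    # each array must sit inside one litter
    arr_lit = pd.DataFrame({"array": arrays, "litter": litters}).drop_duplicates()
    if arr_lit["array"].duplicated().any():
        return None, None
    Q = np.zeros((n, n))
    coefs = np.zeros((n, 2))  # columns: gamma_array, gamma_litter multipliers
    col = 0
    for lit in pd.unique(litters):
        lidx = np.flatnonzero(litters == lit)
        m_l = len(lidx)
        arr_ids = pd.unique(arrays[lidx])
        sizes = {a: int(np.sum(arrays[lidx] == a)) for a in arr_ids}
        if len(set(sizes.values())) != 1:
            return None, None
        m_a = next(iter(sizes.values()))
        k = len(arr_ids)
        # litter mean
        Q[lidx, col] = 1.0 / np.sqrt(m_l)
        coefs[col] = (m_a, m_l)
        col += 1
        # between-array contrasts (constant within array, zero-sum in litter)
        H = _helmert(k)
        for j in range(1, k):
            v = np.zeros(m_l)
            for ai, a in enumerate(arr_ids):
                v[arrays[lidx] == a] = H[ai, j]
            v /= np.linalg.norm(v)
            Q[lidx, col] = v
            coefs[col] = (m_a, 0.0)
            col += 1
        # within-array contrasts
        for a in arr_ids:
            aidx = lidx[arrays[lidx] == a]
            B = _helmert(len(aidx))
            for j in range(1, len(aidx)):
                Q[aidx, col] = B[:, j]
                coefs[col] = (0.0, 0.0)
                col += 1
    return Q, coefs


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclass
class NullModelFit:
    """REML null-model fit: variance components + whitening machinery."""

    sigma2: dict                   # residual + one entry per random factor
    beta: np.ndarray
    beta_names: list
    gammas: np.ndarray             # variance ratios sigma2_k / sigma2_e
    reml_loglik: float
    converged: bool
    n: int
    rank_fixed: int
    structure: _Structure = field(repr=False)
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def sigma2_e(self) -> float:
        return self.sigma2["residual"]

    def total_random_variance(self) -> float:
        return float(sum(self.sigma2.values()))

    def whitener(self):
        """Matrix S with S' S = W^{-1}: y_white = S y has iid errors (x sigma_e)."""
        st = self.structure
        if st.Q is not None:
            d = st.eigvals(self.gammas)
            return (st.Q / np.sqrt(d)).T  # rows scaled: S = D^{-1/2} Q'
        W = st.W(self.gammas)
        L = linalg.cholesky(W, lower=True)
        return linalg.solve_triangular(L, np.eye(len(W)), lower=True)


def _reml_neg2(gammas, st: _Structure, X, y):
    n, p = X.shape
    if st.Q is not None:
        d = st.eigvals(gammas)
        w = 1.0 / d
        Xt, yt = st._Xt, st._yt
        sw = np.sqrt(w)
        Xs = Xt * sw[:, None]
        ys = yt * sw
        logdetW = float(np.sum(np.log(d)))
    else:
        W = st.W(gammas)
        L = linalg.cholesky(W, lower=True)
        Xs = linalg.solve_triangular(L, X, lower=True)
        ys = linalg.solve_triangular(L, y, lower=True)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(L))))
    G = Xs.T @ Xs
    sign, logdetG = np.linalg.slogdet(G)
    beta = np.linalg.solve(G, Xs.T @ ys)
    rss = float(np.sum((ys - Xs @ beta) ** 2))
    s2 = rss / (n - p)
    return (n - p) * np.log(s2) + logdetW + logdetG, beta, s2


def fit_null_model(
    y: np.ndarray,
    design: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
) -> NullModelFit:
    """REML fit of the null mixed model (no QTL term).

    Estimates (sigma2_array, sigma2_litter, sigma2_e) — boundary zeros
    allowed — plus GLS fixed effects at the optimum.
    """
    y = np.asarray(y, float)
    for factor in spec.random:
        if design[factor].nunique() < 2:
            raise ValueError(f"need >= 2 levels of random factor {factor!r}")
    X, names, _ = build_design_matrix(design, spec.fixed)
    _check_confounding(design, spec.fixed, spec.random)
    st = _build_structure(design, spec.random)
    if st.Q is not None:
        st._Xt = st.Q.T @ X
        st._yt = st.Q.T @ y

    def obj(theta):
        return _reml_neg2(np.asarray(theta), st, X, y)[0]

    bounds = [(0.0, 1e4)] * len(spec.random)
    best = None
    for start in ((0.1, 0.1), (1.0, 1.0)):
        theta0 = np.asarray(start[: len(spec.random)])
        res = optimize.minimize(
            obj, theta0, method="Nelder-Mead", bounds=bounds,
            options={"maxiter": 500, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if not best.success:
        res = optimize.minimize(obj, best.x, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 200})
        if res.fun <= best.fun:
            best = res
        if not best.success:
            raise ConvergenceError(
                f"REML optimization failed: {best.message}",
                trace={"nit": best.nit, "x": best.x.tolist(),
                       "fun": float(best.fun)},
            )
    gammas = np.where(best.x < 1e-6, 0.0, best.x)
    crit, beta, s2 = _reml_neg2(gammas, st, X, y)
    sigma2 = {"residual": s2}
    for name, g in zip(spec.random, gammas):
        sigma2[name] = float(g * s2)
    return NullModelFit(
        sigma2=sigma2, beta=beta, beta_names=names, gammas=gammas,
        reml_loglik=-0.5 * crit, converged=bool(best.success),
        n=len(y), rank_fixed=X.shape[1], structure=st, X=X, y=y,
    )


# ---------------------------------------------------------------------------
# GLS scan
# ---------------------------------------------------------------------------

@dataclass
class ScanProfile:
    """Positionwise additive-effect tests for one trait."""

    trait: str
    table: pd.DataFrame            # position, a_hat, se, t, p, df, degenerate
    sigma2: dict
    h2: float
    peak_position: str
    peak_p: float

    def min_p(self) -> float:
        return float(self.table["p"].min())


def scan_transcript(
    y: np.ndarray,
    design: pd.DataFrame,
    ca: pd.DataFrame,
    null_fit: Optional[NullModelFit] = None,
    spec: ModelSpec = ModelSpec(),
    trait: str = "trait",
) -> ScanProfile:
    """GLS t-tests of the additive effect at every scan position.

    ``ca`` is the (samples x positions) additive-coefficient matrix from
    :func:`eqtlcross.origin_prob.compute_ca_matrix`; its rows must cover
    the design's samples.
    """
    y = np.asarray(y, float)
    if null_fit is None:
        null_fit = fit_null_model(y, design, spec)
    C = ca.loc[list(design["sample"])].to_numpy(float)
    S = null_fit.whitener()
    Xs = S @ null_fit.X
    ys = S @ y
    Cs = S @ C
    Q1, _ = np.linalg.qr(Xs)
    ey = ys - Q1 @ (Q1.T @ ys)
    EC = Cs - Q1 @ (Q1.T @ Cs)
    denom = np.sum(EC**2, axis=0)
    n, p = null_fit.n, null_fit.rank_fixed
    df = n - p - 1
    degenerate = denom <= _ALIAS_TOL
    safe = np.where(degenerate, 1.0, denom)
    a_hat = (EC.T @ ey) / safe
    rss = np.sum(ey**2) - a_hat**2 * safe
    s2 = np.maximum(rss / df, 1e-300)
    se = np.sqrt(s2 / safe)
    t = a_hat / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    a_hat[degenerate] = 0.0
    t[degenerate] = 0.0
    se[degenerate] = np.inf
    pvals[degenerate] = 1.0

    table = pd.DataFrame({
        "position": ca.columns, "a_hat": a_hat, "se": se, "t": t,
        "p": pvals, "df": df, "degenerate": degenerate,
    })
    ipeak = int(np.argmin(pvals))
    h2 = variance_explained(a_hat[ipeak], C[:, ipeak], null_fit.sigma2)
    return ScanProfile(
        trait=trait, table=table, sigma2=dict(null_fit.sigma2), h2=h2,
        peak_position=str(ca.columns[ipeak]), peak_p=float(pvals[ipeak]),
    )


def variance_explained(a_hat: float, ca_column: np.ndarray, sigma2: dict) -> float:
    """Fraction of variance attributed to the QTL at a position:
    h2 = a^2 Var(c_a) / (a^2 Var(c_a) + sum of variance components)."""
    qtl_var = float(a_hat) ** 2 * float(np.var(np.asarray(ca_column, float)))
    total = qtl_var + sum(sigma2.values())
    return 0.0 if total == 0 else qtl_var / total


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class EQTLScanner(BaseEstimator):
    """Mixed-model eQTL scan over many transcripts, scikit-learn style.

    Parameters
    ----------
    fixed, random : design columns used as fixed/random effects.
    ca : (samples x positions) additive-coefficient DataFrame; may also be
        passed to :meth:`fit`.

    After ``fit(expression, design)`` the estimator exposes
    ``profiles_`` (long DataFrame of positionwise tests across traits) and
    ``summaries_`` (per-trait peak, variance components and h2).
    """

    def __init__(self, fixed=("dye", "sex", "growth_group"),
                 random=("array", "litter"), ca: Optional[pd.DataFrame] = None):
        self.fixed = fixed
        self.random = random
        self.ca = ca

    def fit(self, X: pd.DataFrame, y: Optional[pd.DataFrame] = None,
            ca: Optional[pd.DataFrame] = None) -> "EQTLScanner":
        """X: expression (traits x samples); y: design table."""
        design = y
        if design is None:
            raise ValueError("the design table must be passed as `y`")
        ca = ca if ca is not None else self.ca
        if ca is None:
            raise ValueError("an additive-coefficient matrix is required")
        spec = ModelSpec(tuple(self.fixed), tuple(self.random))
        profiles, summaries = [], []
        order = list(design["sample"])
        for trait, row in X.loc[:, order].iterrows():
            prof = scan_transcript(row.to_numpy(float), design, ca, spec=spec,
                                   trait=str(trait))
            tab = prof.table.copy()
            tab.insert(0, "trait", prof.trait)
            profiles.append(tab)
            summaries.append({
                "trait": prof.trait, "peak_position": prof.peak_position,
                "peak_p": prof.peak_p, "h2": prof.h2, **{
                    f"sigma2_{k}": v for k, v in prof.sigma2.items()},
            })
        self.profiles_ = pd.concat(profiles, ignore_index=True)
        self.summaries_ = pd.DataFrame(summaries)
        self.n_features_in_ = X.shape[1]
        return self

    def score(self, X=None, y=None) -> float:
        """Mean REML log-likelihood proxy: negative mean peak log10 p."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "summaries_")
        return float(-np.log10(self.summaries_["peak_p"]).mean())
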