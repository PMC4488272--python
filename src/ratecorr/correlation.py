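"""Simple and partial correlation, significance tiers, and variance explained.

Partial Spearman correlation is computed by the two-step residual
procedure: each of the two variables is regressed (ordinary least squares)
on the full conditioning set, and the Spearman correlation of the two
residual vectors is reported.  This is the rank analogue of partial
correlation that stays well defined for non-normal, zero-inflated
variables, at the price of an approximate null distribution.

Significance uses the Spearman t-approximation with n-2 degrees of
freedom on the residuals (the conditioning-set size is *not* subtracted
by default, matching the two-step procedure; a corrected variant is
available via ``df_correction=True``).  Network-level multiplicity is
handled by Benjamini-Hochberg FDR over the network's full p-value family,
with a second, stricter "strong" tier at a fixed raw p-value cutoff.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "CorrelationNetwork",
    "spearman",
    "pearson",
    "partial_corr",
    "partial_spearman",
    "partial_corr_network",
    "assign_tiers",
    "variance_explained",
]

logger = logging.getLogger(__name__)

#: reciprocal-condition-number threshold below which a design is rejected
#: as rank-deficient
RCOND_TOL = 1e-10


@dataclass(frozen=True)
class CorrelationResult:
    """One (pair, method, conditioning set) correlation record."""

    param_a: str
    param_b: str
    rho: float
    p_value: float
    n: int
    method: str = "spearman"
    conditioning_set: tuple[str, ...] = ()
    fdr1: bool | None = None      # BH-adjusted p <= alpha (set by assign_tiers)
    strong: bool | None = None    # raw p <= strong cutoff

    def __post_init__(self):
        if self.param_a in self.conditioning_set or self.param_b in self.conditioning_set:
            raise ValueError("conditioning set must exclude the correlated pair")

    @property
    def tier(self) -> str:
        if self.strong:
            return "strong"
        if self.fdr1:
            return "fdr1"
        return "not_significant"

    @property
    def sign(self) -> str:
        if np.isnan(self.rho):
            return "NA"
        return "+" if self.rho >= 0 else "-"


@dataclass
class CorrelationNetwork:
    """All-pairs correlation results over a parameter set, with tiers."""

    params: list[str]
    results: list[CorrelationResult]
    method: str = "spearman"
    fdr_alpha: float | None = None
    strong_p: float | None = None

    def get(self, a: str, b: str) -> CorrelationResult:
        key = tuple(sorted((a, b)))
        for r in self.results:
            if (r.param_a, r.param_b) == key:
                return r
        raise KeyError(f"no result for pair {key}")

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"param_a": r.param_a, "param_b": r.param_b, "rho": r.rho,
             "p_value": r.p_value, "n": r.n, "tier": r.tier, "sign": r.sign}
            for r in self.results
        ]
        df = pd.DataFrame(rows, columns=["param_a", "param_b", "rho",
                                         "p_value", "n", "tier", "sign"])
        return df.sort_values(["param_a", "param_b"]).reset_index(drop=True)


def _rank_corr_t_test(rho: float, n: int, df: int) -> float:
    """Two-sided p for a correlation via the t approximation."""
    if df <= 0 or np.isnan(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df))


def _corr_of(x: np.ndarray, y: np.ndarray, method: str,
             a: str, b: str, cond: tuple[str, ...], df: int) -> CorrelationResult:
    n = x.size
    if method == "spearman":
        x = stats.rankdata(x)  # mid-ranks: ties get their average rank
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            f"zero variance for pair ({a}, {b}); correlation undefined",
            RuntimeWarning, stacklevel=3,
        )
        return CorrelationResult(a, b, float("nan"), float("nan"), n,
                                 method=method, conditioning_set=cond)
    rho = float(np.corrcoef(x, y)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    return CorrelationResult(a, b, rho, _rank_corr_t_test(rho, n, df), n,
                             method=method, conditioning_set=cond)


def _as_pair(x, y, name_a, name_b):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite (complete-case filter upstream)")
    a, b = sorted((name_a, name_b))
    if (a, b) != (name_a, name_b):
        x, y = y, x
    return x, y, a, b


def spearman(x, y, *, name_a: str = "x", name_b: str = "y") -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks, with a
    two-sided p-value from the t approximation on n-2 degrees of freedom."""
    x, y, a, b = _as_pair(x, y, name_a, name_b)
    return _corr_of(x, y, "spearman", a, b, (), x.size - 2)


def pearson(x, y, *, name_a: str = "x", name_b: str = "y") -> CorrelationResult:
    x, y, a, b = _as_pair(x, y, name_a, name_b)
    return _corr_of(x, y, "pearson", a, b, (), x.size - 2)


def _ols_residuals(y: np.ndarray, design: np.ndarray, colnames) -> np.ndarray:
    """Residuals of OLS of y on the design (which includes the intercept)."""
    gram = design.T @ design
    # reciprocal condition number of the cross-product matrix
    sv = np.linalg.svd(gram, compute_uv=False)
    if sv[0] <= 0 or sv[-1] / sv[0] < RCOND_TOL:
        raise np.linalg.LinAlgError(
            f"rank-deficient design over columns {list(colnames)}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_corr(x, y, Z=None, *, method: str = "spearman",
                 name_a: str = "x", name_b: str = "y",
                 conditioning_names: tuple[str, ...] | None = None,
                 df_correction: bool = False) -> CorrelationResult:
    """Partial correlation of x and y given the covariate matrix Z.

    Both x and y are regressed by OLS on [1, Z]; the correlation of the two
    residual vectors is returned.  With an empty Z this reduces exactly to
    the simple correlation.  ``df_correction=True`` subtracts the number of
    conditioning covariates from the t-test degrees of freedom.
    """
    x, y, a, b = _as_pair(x, y, name_a, name_b)
    if Z is None:
        Z = np.empty((x.size, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != x.size:
        raise ValueError("Z row count must match x and y")
    if not np.isfinite(Z).all():
        raise ValueError("Z must be finite (complete-case filter upstream)")
    if conditioning_names is None:
        conditioning_names = tuple(f"z{i}" for i in range(Z.shape[1]))
    cond = tuple(conditioning_names)
    if Z.shape[1] == 0:
        return _corr_of(x, y, method, a, b, cond, x.size - 2)
    design = np.column_stack([np.ones(x.size), Z])
    rx = _ols_residuals(x, design, ("intercept",) + cond)
    ry = _ols_residuals(y, design, ("intercept",) + cond)
    # a variable perfectly fit by Z leaves numerically-zero residuals:
    # the partial correlation is undefined, not a tiny-noise artifact
    for r, v in ((rx, x), (ry, y)):
        if np.std(r) <= 1e-10 * max(np.std(v), 1.0):
            r[:] = 0.0
    df = x.size - 2 - (Z.shape[1] if df_correction else 0)
    return _corr_of(rx, ry, method, a, b, cond, df)


def partial_spearman(x, y, Z=None, **kwargs) -> CorrelationResult:
    """Partial Spearman correlation (see :func:`partial_corr`)."""
    return partial_corr(x, y, Z, method="spearman", **kwargs)


def partial_corr_network(table: pd.DataFrame, params: list[str] | None = None,
                         *, method: str = "spearman",
                         df_correction: bool = False) -> CorrelationNetwork:
    """All-pairs partial correlation network over ``params``.

    For every unordered pair, the conditioning set is all remaining k-2
    parameters.  The input must be complete-case over ``params``; rows are
    genes.  Per-pair failures (zero-variance residuals) are recorded as
    missing results with a log entry, not raised.
    """
    if params is None:
        params = list(table.columns)
    if len(params) < 3:
        raise ValueError("a partial correlation network requires >= 3 parameters")
    missing = [p for p in params if p not in table.columns]
    if missing:
        raise ValueError(f"parameters absent from table: {missing}")
    sub = table[params].dropna()
    if len(sub) < len(table):
        logger.info("network: dropped %d incomplete rows", len(table) - len(sub))
    data = {p: sub[p].to_numpy(dtype=float) for p in params}
    results = []
    for a, b in itertools.combinations(sorted(params), 2):
        cond = tuple(p for p in params if p not in (a, b))
        Z = np.column_stack([data[p] for p in cond]) if cond else None
        try:
            res = partial_corr(data[a], data[b], Z, method=method,
                               name_a=a, name_b=b, conditioning_names=cond,
                               df_correction=df_correction)
        except np.linalg.LinAlgError as exc:
            logger.warning("pair (%s, %s) failed: %s", a, b, exc)
            res = CorrelationResult(a, b, float("nan"), float("nan"),
                                    len(sub), method=method,
                                    conditioning_set=cond)
        results.append(res)
    return CorrelationNetwork(params=sorted(params), results=results,
                              method=method)


def assign_tiers(network: CorrelationNetwork, *, fdr_alpha: float = 0.01,
                 strong_p: float = 0.0005) -> CorrelationNetwork:
    """Assign significance tiers over the network's full p-value family.

    ``fdr1``: Benjamini-Hochberg adjusted p <= ``fdr_alpha`` (default 1%
    FDR).  ``strong``: raw p <= ``strong_p`` (default 0.0005).  The two
    criteria are applied independently, as in the original two-tier
    reporting convention.
    """
    pvals = np.array([r.p_value for r in network.results], dtype=float)
    ok = np.isfinite(pvals)
    adjusted = np.full(pvals.shape, np.nan)
    if ok.any():
        _, adj, _, _ = multipletests(pvals[ok], method="fdr_bh")
        adjusted[ok] = adj
    results = [
        replace(r,
                fdr1=bool(ok[i]) and bool(adjusted[i] <= fdr_alpha),
                strong=bool(ok[i]) and bool(pvals[i] <= strong_p))
        for i, r in enumerate(network.results)
    ]
    return CorrelationNetwork(params=network.params, results=results,
                              method=network.method,
                              fdr_alpha=fdr_alpha, strong_p=strong_p)


def variance_explained(table: pd.DataFrame, target: str,
                       predictors: list[str]) -> float:
    """Fraction of the target's variance explained by the predictors:
    the coefficient of determination R^2 of the OLS fit of ``target`` on
    all ``predictors`` jointly (transformed scale)."""
    if target in predictors:
        raise ValueError("target must not appear among the predictors")
    sub = table[[target] + list(predictors)].dropna()
    y = sub[target].to_numpy(dtype=float)
    X = sub[list(predictors)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    resid = _ols_residuals(y, design, ["intercept"] + list(predictors))
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("target has zero variance")
    return float(1.0 - np.sum(resid ** 2) / ss_tot)
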