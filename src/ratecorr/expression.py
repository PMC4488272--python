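"""Expression post-processing and per-gene expression summaries.

The pipeline mirrors standard multi-tissue RNA-seq treatment for
rank-based downstream analysis:

1. multiply linear-scale values by 10^6 (so values are not pushed below 1,
   which would go negative after the log),
2. replace exact zeros by 1.0001 (so their log2 is a small positive number,
   log2(1.0001) ~ 1.44e-4, rather than -inf),
3. log2 transform,
4. quantile-normalize across tissue columns.

Tissue specificity is Yanai's tau: 0 for uniformly (broadly) expressed
genes, 1 for genes expressed in a single tissue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = [
    "normalize_expression",
    "quantile_normalize",
    "compute_tau",
    "summarize_expression",
]

#: value substituted for an exact zero before the log2 step
ZERO_REPLACEMENT = 1.0001
SCALE = 1e6


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns: each column's order statistics are replaced
    by the mean of the corresponding order statistics across all columns.

    Ties within a column receive the mean of the reference values of the
    ranks they span (the behaviour of limma's ``normalizeQuantiles`` with
    ``ties=TRUE``), which matters for zero-inflated columns.  Tie averaging
    preserves each column's sum exactly, so column means are equal after
    normalization; the full value multiset is identical across columns
    whenever columns are tie-free.
    """
    arr = df.to_numpy(dtype=float)
    n, _ = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # average reference values over tied observations
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Run the full normalization pipeline on a raw linear-scale matrix.

    Raises if the matrix is already normalized (the pipeline must not be
    applied twice) or contains negative values.
    """
    if matrix.is_normalized:
        raise ValueError("matrix is already normalized; refusing to re-apply")
    values = matrix.values.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("raw expression matrix contains negative values")
    scaled = values * SCALE
    scaled[scaled == 0] = ZERO_REPLACEMENT
    logged = pd.DataFrame(np.log2(scaled), index=matrix.values.index,
                          columns=matrix.values.columns)
    normalized = quantile_normalize(logged)
    return ExpressionMatrix(values=normalized, is_normalized=True)


def compute_tau(profile: np.ndarray | pd.Series) -> float:
    """Yanai tissue-specificity index of one gene's expression profile.

    tau = sum_i (1 - x_i / max(x)) / (N - 1), computed on the profile with
    negative (log-scale) values floored at zero.  Returns NaN for a gene
    with no positive expression anywhere (tau undefined).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires a 1-D profile over at least 2 tissues")
    x = np.clip(x, 0.0, None)
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def summarize_expression(matrix: ExpressionMatrix,
                         tissue_prefix: str = "expr_") -> pd.DataFrame:
    """Per-gene expression summary from a normalized matrix.

    Returns a DataFrame indexed by gene with ``median_expr``, ``max_expr``,
    ``tau`` and one ``expr_<tissue>`` column per tissue (all in the
    normalized log2 scale).
    """
    if not matrix.is_normalized:
        raise ValueError("summarize_expression requires a normalized matrix")
    v = matrix.values
    out = pd.DataFrame(index=v.index)
    out["median_expr"] = v.median(axis=1)
    out["max_expr"] = v.max(axis=1)
    out["tau"] = [compute_tau(row) for row in v.to_numpy()]
    for tissue in v.columns:
        out[f"{tissue_prefix}{tissue}"] = v[tissue]
    return out
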