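"""The variable-transformation ledger applied to feature tables before
correlation analysis.

Rules
-----
``log2_offset``
    If the column contains zeros, add its minimal non-zero value to every
    entry, then take log2; columns without zeros are logged directly.
    Applied to expression-derived quantities that did not pass through the
    RNA-seq pipeline, gene-structure sizes, omega0, tau and paralog counts.
``fourth_root``
    x -> x**(1/4); applied to p1 and delta_lnl, whose distributions pile up
    near zero.
``identity``
    Left unchanged: fractions, ordinals, binaries, and per-tissue
    expression columns (already log2/quantile-treated upstream).

Every rule is strictly monotone on its domain, so simple (unconditional)
Spearman correlations are invariant to the ledger; only the residual step
of partial correlation is affected.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_TRANSFORMS", "transform_column", "transform_table"]

VALID_RULES = frozenset({"log2_offset", "fourth_root", "identity"})

#: parameter -> rule for the default analysis set
DEFAULT_TRANSFORMS: dict[str, str] = {
    "omega0": "log2_offset",
    "p1": "fourth_root",
    "delta_lnl": "fourth_root",
    "tau": "log2_offset",
    "median_expr": "identity",   # already log2 from the expression pipeline
    "max_expr": "identity",
    "intron_length": "log2_offset",
    "intron_number": "log2_offset",
    "cds_length": "log2_offset",
    "paralog_number": "log2_offset",
    "gc_content": "identity",
    "stage_number": "identity",
    "phyletic_age": "identity",
    "recombination_rate": "log2_offset",
    "connectivity": "identity",
    "essentiality": "identity",
}


def transform_column(values: pd.Series | np.ndarray, rule: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if rule == "identity":
        return x.copy()
    if rule == "fourth_root":
        if (obs < 0).any():
            raise ValueError("fourth_root transform requires non-negative values")
        return x ** 0.25
    if rule == "log2_offset":
        if (obs < 0).any():
            raise ValueError("log2_offset transform requires non-negative values")
        offset = 0.0
        if (obs == 0).any():
            nonzero = obs[obs > 0]
            if nonzero.size == 0:
                raise ValueError("log2_offset transform on an all-zero column")
            offset = nonzero.min()
        return np.log2(x + offset)
    raise ValueError(f"unknown transform rule {rule!r}")


def transform_table(table: pd.DataFrame,
                    spec: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Return a transformed view of the feature table.

    ``spec`` maps column name -> rule; columns not named in the spec
    (e.g. per-tissue expression) are passed through unchanged.  With no
    spec, :data:`DEFAULT_TRANSFORMS` is used for whichever of its columns
    are present.
    """
    if spec is None:
        spec = {k: v for k, v in DEFAULT_TRANSFORMS.items() if k in table.columns}
    bad = set(spec.values()) - VALID_RULES
    if bad:
        raise ValueError(f"unknown transform rules: {sorted(bad)}")
    missing = [c for c in spec if c not in table.columns]
    if missing:
        raise ValueError(f"transform spec names absent columns: {missing}")
    out = table.copy()
    for col, rule in spec.items():
        try:
            out[col] = transform_column(table[col], rule)
        except ValueError as exc:
            raise ValueError(f"column {col!r}: {exc}") from exc
    return out
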