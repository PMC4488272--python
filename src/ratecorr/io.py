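"""Reading and writing the package's TSV artifacts.

All tables are tab-separated UTF-8 with '.' as the decimal mark; missing
values are written as ``NA``.  Readers validate strictly and refuse to
coerce corrupted input (a string inside a numeric column is an error, not
a NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

__all__ = [
    "ExpressionMatrix",
    "ColumnSpec",
    "FeatureSchema",
    "DEFAULT_FEATURE_SCHEMA",
    "read_expression",
    "write_expression",
    "read_feature_table",
    "write_feature_table",
    "complete_cases",
    "write_edge_list",
    "read_edge_list",
    "load_config",
    "save_config",
]


@dataclass
class ExpressionMatrix:
    """A genes x tissues expression matrix.

    ``values`` is a pandas DataFrame indexed by gene identifier with one
    column per tissue.  Raw matrices hold linear-scale, FPKM-like values;
    after :func:`ratecorr.expression.normalize_expression` the values are
    log2, quantile-normalized, and ``is_normalized`` is set.
    """

    values: pd.DataFrame
    is_normalized: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate tissue names: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression for gene {v.index[i]!r}, tissue {v.columns[j]!r}"
            )
        if not self.is_normalized and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression for gene {v.index[i]!r}, tissue {v.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _read_tsv_strict(path, index_name: str) -> pd.DataFrame:
    # check the header ourselves: pandas silently mangles duplicates
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    if len(set(cols)) != len(cols):
        dups = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"duplicate tissue/column names in header: {dups}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False)
    df.index.name = index_name
    df.index = df.index.astype(str)
    return df


def _to_numeric_strict(df: pd.DataFrame, allow_na: bool) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        raw = df[col]
        mask_na = raw == NA_TOKEN
        if mask_na.any() and not allow_na:
            gene = raw.index[mask_na][0]
            raise ValueError(f"missing value (NA) for gene {gene!r} in column {col!r}")
        converted = pd.to_numeric(raw.where(~mask_na), errors="coerce")
        bad = converted.isna() & ~mask_na
        if bad.any():
            gene = raw.index[bad][0]
            raise ValueError(
                f"non-numeric value {raw[bad].iloc[0]!r} for gene {gene!r} "
                f"in column {col!r}"
            )
        out[col] = converted.astype(float)
    return pd.DataFrame(out, index=df.index)


def read_expression(path, *, is_normalized: bool = False) -> ExpressionMatrix:
    """Read a gene x tissue expression TSV (header row of tissue names,
    first column ``gene_id``)."""
    df = _read_tsv_strict(path, "gene_id")
    values = _to_numeric_strict(df, allow_na=False)
    return ExpressionMatrix(values=values, is_normalized=is_normalized)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    # default float formatting is shortest round-trip repr: exact re-read
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class ColumnSpec:
    """Role of one feature-table column: value bounds and the bound type."""

    lo: float | None = None
    hi: float | None = None
    # "open_lo" means the lower bound is strict (value must exceed lo)
    open_lo: bool = False
    open_hi: bool = False
    integer: bool = False

    def validate(self, series: pd.Series, name: str) -> None:
        x = series.dropna()
        if self.lo is not None:
            bad = x <= self.lo if self.open_lo else x < self.lo
            if bad.any():
                gene = x.index[bad][0]
                raise ValueError(
                    f"{name}={x[bad].iloc[0]} out of range for gene {gene!r}"
                )
        if self.hi is not None:
            bad = x >= self.hi if self.open_hi else x > self.hi
            if bad.any():
                gene = x.index[bad][0]
                raise ValueError(
                    f"{name}={x[bad].iloc[0]} out of range for gene {gene!r}"
                )
        if self.integer and not np.allclose(x, np.round(x)):
            bad = ~np.isclose(x, np.round(x))
            gene = x.index[bad][0]
            raise ValueError(f"{name}={x[bad].iloc[0]} is not integral (gene {gene!r})")


@dataclass
class FeatureSchema:
    """Declares the expected columns of a gene feature table.

    ``required`` columns must be present in the file; ``optional`` columns
    are validated when present.  Columns in the file but in neither set are
    kept untouched (e.g. per-tissue expression columns).
    """

    required: Mapping[str, ColumnSpec] = field(default_factory=dict)
    optional: Mapping[str, ColumnSpec] = field(default_factory=dict)

    def validate(self, table: pd.DataFrame) -> None:
        for name, spec in self.required.items():
            if name not in table.columns:
                raise ValueError(f"required column {name!r} absent from feature table")
            spec.validate(table[name], name)
        for name, spec in self.optional.items():
            if name in table.columns:
                spec.validate(table[name], name)


#: Default schema for the analysis parameter set: branch-site rate components
#: (omega0 = dN/dS on the purifying class, p1 = neutral-site proportion,
#: delta_lnl = positive-selection LRT statistic), gene-structure covariates,
#: and the global expression parameters.
DEFAULT_FEATURE_SCHEMA = FeatureSchema(
    required={
        "omega0": ColumnSpec(lo=0.0, open_lo=True),
        "p1": ColumnSpec(lo=0.0, hi=1.0),
        "delta_lnl": ColumnSpec(lo=0.0),
        "gc_content": ColumnSpec(lo=0.0, hi=1.0, open_lo=True, open_hi=True),
        "intron_length": ColumnSpec(lo=0.0),
        "intron_number": ColumnSpec(lo=0.0, integer=True),
        "cds_length": ColumnSpec(lo=0.0, open_lo=True),
        "paralog_number": ColumnSpec(lo=0.0, integer=True),
        "phyletic_age": ColumnSpec(lo=1, hi=6, integer=True),
        "stage_number": ColumnSpec(lo=1, hi=10, integer=True),
    },
    optional={
        "tau": ColumnSpec(lo=0.0, hi=1.0),
        "median_expr": ColumnSpec(),
        "max_expr": ColumnSpec(),
        "recombination_rate": ColumnSpec(lo=0.0),
        "connectivity": ColumnSpec(lo=0.0),
        "essentiality": ColumnSpec(lo=0, hi=1, integer=True),
    },
)


def read_feature_table(path, schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Read a gene feature TSV; ``NA`` cells become explicit missing values.

    Raises if a schema-required column is absent or any value violates its
    declared range.
    """
    if schema is None:
        schema = DEFAULT_FEATURE_SCHEMA
    df = _read_tsv_strict(path, "gene_id")
    table = _to_numeric_strict(df, allow_na=True)
    schema.validate(table)
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", na_rep=NA_TOKEN)


def complete_cases(table: pd.DataFrame, params: Sequence[str]) -> pd.DataFrame:
    """Listwise-drop genes missing any of ``params``; the dropped count is logged.

    The analysis is complete-case: a gene enters the correlation network only
    if every active parameter is observed for it.
    """
    missing = [p for p in params if p not in table.columns]
    if missing:
        raise ValueError(f"parameters absent from table: {missing}")
    sub = table.dropna(subset=list(params))
    n_dropped = len(table) - len(sub)
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d genes",
                    n_dropped, len(table))
    return sub


EDGE_COLUMNS = ["param_a", "param_b", "rho", "p_value", "n", "tier", "sign"]


def write_edge_list(network, path) -> None:
    """Write a correlation network as a deterministic, pair-sorted edge TSV."""
    df = network.to_edge_frame()
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN,
              float_format="%.12f")


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"param_a": str, "param_b": str,
                                            "tier": str, "sign": str},
                     keep_default_na=False, na_values=[NA_TOKEN])
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list missing columns: {missing}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
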