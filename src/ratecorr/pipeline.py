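"""Orchestration of the full analysis design.

Four entry points mirror the study design:

- :func:`run_global` — the all-pairs partial Spearman network over the
  core parameter set (rate components, global expression parameters,
  gene-structure covariates), with significance tiers and the variance
  of omega0 explained by the non-rate parameters;
- :func:`run_per_tissue` — partial correlation between each tissue's
  expression column and each rate component separately;
- :func:`run_subset_specific` — the per-tissue analysis restricted to
  tissue-specific genes (tau above a threshold);
- :func:`run_toy` — the height/legs demonstration that partial
  correlation separates causal structures that simple correlation
  cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import (CorrelationNetwork, CorrelationResult, assign_tiers,
                          partial_corr, partial_corr_network, spearman,
                          variance_explained)
from .io import complete_cases
from .transforms import transform_table

__all__ = [
    "AnalysisConfig",
    "GlobalResult",
    "TissueAnalysisResult",
    "ToyReport",
    "RATE_PARAMS",
    "STRUCTURAL_PARAMS",
    "GLOBAL_EXPRESSION_PARAMS",
    "CORE_PARAMS",
    "run_global",
    "run_per_tissue",
    "run_subset_specific",
    "run_toy",
]

logger = logging.getLogger(__name__)

#: evolutionary-rate components from the branch-site model
RATE_PARAMS = ("omega0", "p1", "delta_lnl")
#: structural / evolutionary gene covariates
STRUCTURAL_PARAMS = ("gc_content", "intron_length", "intron_number",
                     "cds_length", "paralog_number", "phyletic_age",
                     "stage_number")
#: global expression parameters derived from the expression matrix
GLOBAL_EXPRESSION_PARAMS = ("tau", "median_expr", "max_expr")
#: the 13-parameter core analysis set
CORE_PARAMS = RATE_PARAMS + GLOBAL_EXPRESSION_PARAMS + STRUCTURAL_PARAMS


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and switches for a pipeline run (defaults as published:
    FDR 1%, strong tier at raw p <= 0.0005, tissue-specific tau > 0.2)."""

    fdr_alpha: float = 0.01
    strong_p: float = 0.0005
    tau_threshold: float = 0.2
    min_subset_size: int = 50
    method: str = "spearman"
    df_correction: bool = False
    #: if True, per-tissue correlations also condition on tau / median /
    #: max expression (stricter; risks conditioning away the signal, since
    #: per-tissue expression is a component of all three)
    condition_on_global_expression: bool = False
    transform_spec: dict | None = None
    tissue_prefix: str = "expr_"


@dataclass
class GlobalResult:
    network: CorrelationNetwork
    edges: pd.DataFrame
    n_genes: int
    n_dropped: int
    variance_explained_omega0: float


def run_global(features: pd.DataFrame, params: list[str] | None = None,
               config: AnalysisConfig | None = None) -> GlobalResult:
    """All-pairs partial correlation network over the core parameter set.

    The feature table is complete-case filtered over the active
    parameters, passed through the transformation ledger, and every
    unordered pair is conditioned on the remaining parameters.  Also
    reports the R^2 of omega0 on the non-rate parameters.
    """
    config = config or AnalysisConfig()
    if params is None:
        params = [p for p in CORE_PARAMS if p in features.columns]
    if len(params) < 3:
        raise ValueError("global analysis requires at least 3 parameters")
    cc = complete_cases(features, params)
    transformed = transform_table(cc[params], config.transform_spec)
    network = partial_corr_network(transformed, params, method=config.method,
                                   df_correction=config.df_correction)
    network = assign_tiers(network, fdr_alpha=config.fdr_alpha,
                           strong_p=config.strong_p)
    non_rate = [p for p in params if p not in RATE_PARAMS]
    ve = float("nan")
    if "omega0" in params and non_rate:
        ve = variance_explained(transformed, "omega0", non_rate)
    logger.info("global network: %d genes (%d dropped), R^2(omega0)=%.4f",
                len(cc), len(features) - len(cc), ve)
    return GlobalResult(network=network, edges=network.to_edge_frame(),
                        n_genes=len(cc), n_dropped=len(features) - len(cc),
                        variance_explained_omega0=ve)


@dataclass
class TissueAnalysisResult:
    """Per-tissue correlation results: one block per (tissue, target)."""

    network: CorrelationNetwork
    edges: pd.DataFrame
    tissues: list[str]
    targets: list[str]
    conditioning: list[str]
    n_genes: int
    tissue_groups: dict = field(default_factory=dict)  # metadata only

    def block(self, tissue: str, target: str) -> CorrelationResult:
        return self.network.get(tissue, target)


def _tissue_columns(features: pd.DataFrame, prefix: str) -> list[str]:
    return [c for c in features.columns if c.startswith(prefix)]


def run_per_tissue(features: pd.DataFrame,
                   targets: tuple[str, ...] = RATE_PARAMS,
                   config: AnalysisConfig | None = None,
                   tissues: list[str] | None = None,
                   tissue_groups: dict | None = None) -> TissueAnalysisResult:
    """Partial correlation of each tissue's expression with each target.

    For tissue t and target r, the conditioning set is the structural
    covariates plus the other rate components — by default *excluding* the
    global expression parameters, since per-tissue expression is a
    component of tau/median/max and conditioning on them would absorb the
    signal under study (switchable via
    ``config.condition_on_global_expression``).  One Benjamini-Hochberg
    family spans all (tissue, target) pairs of the run.
    """
    config = config or AnalysisConfig()
    if tissues is None:
        tissues = _tissue_columns(features, config.tissue_prefix)
    if not tissues:
        raise ValueError("no per-tissue expression columns found")
    missing = [t for t in tissues if t not in features.columns]
    if missing:
        raise ValueError(f"tissue columns absent from table: {missing}")
    targets = [t for t in targets]
    conditioning = [p for p in STRUCTURAL_PARAMS if p in features.columns]
    if config.condition_on_global_expression:
        conditioning += [p for p in GLOBAL_EXPRESSION_PARAMS
                         if p in features.columns]
    active = sorted(set(targets) | set(conditioning) | set(tissues))
    cc = complete_cases(features, active)
    base_cols = sorted(set(targets) | set(conditioning))
    transformed = transform_table(cc[base_cols], config.transform_spec)
    results = []
    for tissue in tissues:
        expr = cc[tissue].to_numpy(dtype=float)
        for target in targets:
            cond = [p for p in conditioning if p != target]
            cond += [r for r in targets if r != target]
            cond = sorted(set(cond))
            Z = transformed[cond].to_numpy(dtype=float)
            res = partial_corr(expr, transformed[target].to_numpy(dtype=float),
                               Z, method=config.method, name_a=tissue,
                               name_b=target, conditioning_names=tuple(cond),
                               df_correction=config.df_correction)
            results.append(res)
    network = CorrelationNetwork(params=sorted(set(tissues) | set(targets)),
                                 results=results, method=config.method)
    network = assign_tiers(network, fdr_alpha=config.fdr_alpha,
                           strong_p=config.strong_p)
    edges = network.to_edge_frame()
    return TissueAnalysisResult(network=network, edges=edges,
                                tissues=list(tissues), targets=targets,
                                conditioning=conditioning, n_genes=len(cc),
                                tissue_groups=tissue_groups or {})


def run_subset_specific(features: pd.DataFrame,
                        tau_threshold: float | None = None,
                        config: AnalysisConfig | None = None,
                        **per_tissue_kwargs) -> TissueAnalysisResult:
    """The per-tissue analysis restricted to tissue-specific genes
    (tau strictly above the threshold, default 0.2)."""
    config = config or AnalysisConfig()
    if tau_threshold is None:
        tau_threshold = config.tau_threshold
    if "tau" not in features.columns:
        raise ValueError("tau column required for the tissue-specific subset")
    subset = features[features["tau"] > tau_threshold]
    logger.info("tissue-specific subset (tau > %g): %d of %d genes",
                tau_threshold, len(subset), len(features))
    if len(subset) < config.min_subset_size:
        raise ValueError(
            f"tissue-specific subset has {len(subset)} genes, fewer than the "
            f"minimum {config.min_subset_size}"
        )
    return run_per_tissue(subset, config=config, **per_tissue_kwargs)


@dataclass
class ToyReport:
    """Simple and partial 3x3 correlation patterns for both toy cases."""

    simple: dict[str, pd.DataFrame]
    partial: dict[str, pd.DataFrame]
    case_a_ok: bool
    case_b_ok: bool

    def summary(self) -> str:
        lines = []
        for case in ("a", "b"):
            lines.append(f"case {case}: simple correlations")
            lines.append(self.simple[case].round(3).to_string())
            lines.append(f"case {case}: partial correlations "
                         "(each pair given the third variable)")
            lines.append(self.partial[case].round(3).to_string())
        lines.append(f"case a discrimination holds: {self.case_a_ok}")
        lines.append(f"case b discrimination holds: {self.case_b_ok}")
        return "\n".join(lines)


def _corr_matrices(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols = list(df.columns)
    simple = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    partial = simple.copy()
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            others = [c for c in cols if c not in (a, b)]
            s = spearman(df[a], df[b], name_a=a, name_b=b).rho
            p = partial_corr(df[a], df[b], df[others].to_numpy(),
                             name_a=a, name_b=b,
                             conditioning_names=tuple(others)).rho
            simple.loc[a, b] = simple.loc[b, a] = s
            partial.loc[a, b] = partial.loc[b, a] = p
    return simple, partial


def run_toy(n: int = 5000, seed: int = 1, *, strong: float = 0.8,
            null_tol: float = 0.05) -> ToyReport:
    """Generate both toy cases and check that partial correlation
    discriminates them: in case a the two legs are conditionally
    uncorrelated given height; in case b the right leg is conditionally
    uncorrelated with height given the left leg, while the legs stay
    strongly partially correlated."""
    from .simulate import generate_toy

    simple, partial = {}, {}
    for case in ("a", "b"):
        df = generate_toy(case, n, seed)
        simple[case], partial[case] = _corr_matrices(df)
    a_ok = (
        (simple["a"].to_numpy()[np.triu_indices(3, 1)] > strong).all()
        and abs(partial["a"].loc["left_leg", "right_leg"]) < null_tol
    )
    b_ok = (
        (simple["b"].to_numpy()[np.triu_indices(3, 1)] > strong).all()
        and abs(partial["b"].loc["right_leg", "height"]) < null_tol
        and partial["b"].loc["left_leg", "right_leg"] > 0.5
    )
    return ToyReport(simple=simple, partial=partial,
                     case_a_ok=bool(a_ok), case_b_ok=bool(b_ok))
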