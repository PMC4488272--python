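"""Synthetic gene feature tables and expression matrices with known
planted structure.

The dependence mechanism is a Gaussian copula: a latent multivariate
normal layer carries the planted correlation (or causal-DAG) structure,
and per-parameter marginal transforms then reshape each column into the
skewed, count-valued or zero-inflated form typical of real gene tables.
Because every marginal transform is monotone non-decreasing, rank-based
dependence survives the reshaping (up to ties introduced deliberately by
zero inflation and discretization), so a rank-based analysis pipeline can
be validated against closed-form expectations.

For a bivariate Gaussian with correlation r, the population Spearman
correlation is (6/pi) * arcsin(r/2); :func:`gaussian_rank_corr` exposes
this map and :func:`planted_partial_spearman` combines it with the
precision-matrix identity for partial correlations, giving the oracle
values that estimated partial Spearman networks are checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticFeatures",
    "generate_features",
    "generate_expression",
    "generate_toy",
    "gaussian_rank_corr",
    "planted_partial_pearson",
    "planted_partial_spearman",
]


def gaussian_rank_corr(r: float | np.ndarray) -> float | np.ndarray:
    """Population Spearman correlation of a bivariate Gaussian with
    Pearson correlation ``r``: (6/pi) * arcsin(r/2)."""
    return (6.0 / np.pi) * np.arcsin(np.asarray(r) / 2.0)


def planted_partial_pearson(corr: np.ndarray) -> np.ndarray:
    """Matrix of pairwise partial correlations (each pair conditioned on
    all remaining variables) implied by a correlation matrix, via the
    precision-matrix identity rho_ij.rest = -P_ij / sqrt(P_ii * P_jj)."""
    P = np.linalg.inv(np.asarray(corr, dtype=float))
    d = np.sqrt(np.diag(P))
    partial = -P / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial


def planted_partial_spearman(corr: np.ndarray) -> np.ndarray:
    """Planted partial structure on the Spearman scale: the Gaussian
    rank-correlation map applied to the residual (partial) correlations."""
    partial = planted_partial_pearson(corr)
    out = gaussian_rank_corr(partial)
    np.fill_diagonal(out, 1.0)
    return out


def _check_correlation_matrix(corr: np.ndarray, names) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    k = len(names)
    if corr.shape != (k, k):
        raise ValueError(f"latent_corr must be {k}x{k} for {k} parameters")
    if not np.allclose(corr, corr.T):
        raise ValueError("latent_corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("latent_corr must have a unit diagonal")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 0:
        raise ValueError(
            f"latent_corr is not positive definite (eigenvalue {eigvals.min():.3g})"
        )
    return corr


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of a synthetic gene table and its planted
    dependence structure.

    Exactly one of ``latent_corr`` (target correlation matrix over
    ``params``) or ``causal_edges`` (list of ``(parent, child,
    coefficient, noise_sd)``; parent-less nodes are standard normal) is
    given.  ``marginals`` maps a parameter to a marginal descriptor:

    - ``"normal"`` — latent Gaussian kept as is;
    - ``"lognormal"`` — exponentiated;
    - ``"uniform"`` — probability-integral transform to (0, 1);
    - ``"exponential"`` — unit-rate exponential quantile;
    - ``"count:<lam>"`` — Poisson(lam) quantile (integer, tied);
    - ``"ordinal:<k>"`` — equiprobable ordinal levels 1..k;
    - ``"zero_inflate:<p>:<base>"`` — the lowest fraction ``p`` of the
      latent values become exact zeros; the rest follow ``<base>``.

    Expression structure: ``tissue_profile_mix`` is the fraction of
    tissue-specific genes (each expressed in a single dominant tissue,
    with fraction ``specific_leak`` of its magnitude leaking uniformly
    into the remaining tissues); the rest are broadly expressed with
    log2-scale tissue noise ``broad_noise_sd``.  ``expression_link`` adds
    ``coeff * latent[param]`` to every gene's log2 magnitude;
    ``tissue_links`` entries ``(tissue_index, param, coeff)`` do the same
    for a single tissue, planting per-tissue expression-covariate
    dependence.  ``zero_inflation`` zeroes each expression cell
    independently with the stated probability.
    """

    params: tuple[str, ...]
    n_genes: int
    seed: int
    latent_corr: np.ndarray | None = None
    causal_edges: tuple[tuple[str, str, float, float], ...] | None = None
    marginals: dict = field(default_factory=dict)
    n_tissues: int = 10
    tissue_profile_mix: float = 0.0
    specific_leak: float = 0.0
    broad_noise_sd: float = 0.25
    expr_base_mean: float = 3.0
    expr_base_sd: float = 2.0
    expression_link: dict = field(default_factory=dict)
    tissue_links: tuple[tuple[int, str, float], ...] = ()
    zero_inflation: float = 0.0

    def __post_init__(self):
        if (self.latent_corr is None) == (self.causal_edges is None):
            raise ValueError("give exactly one of latent_corr or causal_edges")
        if not 0.0 <= self.tissue_profile_mix <= 1.0:
            raise ValueError("tissue_profile_mix must be in [0, 1]")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation probability must be in [0, 1]")
        unknown = set(self.marginals) - set(self.params)
        if unknown:
            raise ValueError(f"marginals name unknown parameters: {sorted(unknown)}")


@dataclass
class SyntheticFeatures:
    """A generated feature table with its planted structure kept alongside:
    ``latent`` holds the pre-marginal Gaussian layer, ``spec`` the recipe."""

    table: pd.DataFrame
    latent: pd.DataFrame
    spec: SyntheticSpec


def _apply_marginal(z: np.ndarray, descriptor: str) -> np.ndarray:
    """Monotone marginal transform of a standard-normal column."""
    parts = descriptor.split(":")
    kind = parts[0]
    if kind == "normal":
        return z.copy()
    if kind == "lognormal":
        return np.exp(z)
    u = stats.norm.cdf(z)
    if kind == "uniform":
        return u
    if kind == "exponential":
        return -np.log1p(-u)
    if kind == "count":
        lam = float(parts[1])
        return stats.poisson.ppf(u, lam)
    if kind == "ordinal":
        k = int(parts[1])
        return np.minimum(np.floor(u * k), k - 1) + 1
    if kind == "zero_inflate":
        p = float(parts[1])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"zero-inflation probability {p} outside [0, 1]")
        base = ":".join(parts[2:]) if len(parts) > 2 else "lognormal"
        out = _apply_marginal(z, base)
        out = out - (out.min() if out.min() < 0 else 0.0)
        out[u <= p] = 0.0
        return out
    raise ValueError(f"unknown marginal descriptor {descriptor!r}")


def _latent_from_dag(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    children = {child for _, child, _, _ in spec.causal_edges}
    values: dict[str, np.ndarray] = {}
    remaining = list(spec.params)
    # Kahn-style sweep: a node is ready once all its parents are generated
    while remaining:
        progressed = False
        for name in list(remaining):
            in_edges = [(p, c, sd) for p, ch, c, sd in spec.causal_edges
                        if ch == name]
            if any(p not in values for p, _, _ in in_edges):
                continue
            if name not in children:
                values[name] = rng.standard_normal(spec.n_genes)
            else:
                acc = np.zeros(spec.n_genes)
                for p, coeff, _ in in_edges:
                    acc = acc + coeff * values[p]
                # one noise term per child; its SD is taken from the first edge
                acc = acc + in_edges[0][2] * rng.standard_normal(spec.n_genes)
                values[name] = acc
            remaining.remove(name)
            progressed = True
        if not progressed:
            raise ValueError(f"causal_edges contain a cycle involving {remaining}")
    latent = pd.DataFrame({p: values[p] for p in spec.params})
    # standardize so marginal transforms see a unit-scale column
    return (latent - latent.mean()) / latent.std(ddof=0)


def generate_features(spec: SyntheticSpec) -> SyntheticFeatures:
    """Draw a gene feature table from the spec's planted structure.

    Deterministic given the spec (including its seed).  The latent Gaussian
    layer is returned alongside the table so downstream generators and
    tests can refer to the planted values directly.
    """
    rng = np.random.default_rng([int(spec.seed), 0])
    if spec.latent_corr is not None:
        corr = _check_correlation_matrix(spec.latent_corr, spec.params)
        L = np.linalg.cholesky(corr)
        z = rng.standard_normal((spec.n_genes, len(spec.params))) @ L.T
        latent = pd.DataFrame(z, columns=list(spec.params))
    else:
        latent = _latent_from_dag(spec, rng)
    gene_ids = [f"g{i:06d}" for i in range(spec.n_genes)]
    latent.index = pd.Index(gene_ids, name="gene_id")
    table = pd.DataFrame(index=latent.index)
    for p in spec.params:
        table[p] = _apply_marginal(latent[p].to_numpy(),
                                   spec.marginals.get(p, "normal"))
    return SyntheticFeatures(table=table, latent=latent, spec=spec)


def generate_expression(spec: SyntheticSpec,
                        features: SyntheticFeatures) -> ExpressionMatrix:
    """Draw a raw, linear-scale expression matrix tied to the feature table.

    Each gene has a log2 magnitude (base draw plus the planted
    ``expression_link`` contributions).  Tissue-specific genes put all
    their mass in one dominant tissue (minus the configured leak); broad
    genes get near-uniform profiles with mild log-scale noise.
    """
    if len(features.table) != spec.n_genes:
        raise ValueError("feature table row count does not match spec.n_genes")
    rng = np.random.default_rng([int(spec.seed), 1])
    n, t = spec.n_genes, spec.n_tissues
    log2_mag = (spec.expr_base_mean
                + spec.expr_base_sd * rng.standard_normal(n))
    for param, coeff in spec.expression_link.items():
        log2_mag = log2_mag + coeff * features.latent[param].to_numpy()
    magnitude = 2.0 ** log2_mag

    is_specific = rng.random(n) < spec.tissue_profile_mix
    dominant = rng.integers(0, t, size=n)
    values = np.empty((n, t))
    broad_noise = 2.0 ** (spec.broad_noise_sd * rng.standard_normal((n, t)))
    values[:] = magnitude[:, None] * broad_noise
    if is_specific.any():
        spec_rows = np.where(is_specific)[0]
        leak = spec.specific_leak
        prof = np.full((spec_rows.size, t), leak / max(t - 1, 1))
        prof[np.arange(spec_rows.size), dominant[spec_rows]] = 1.0 - leak
        values[spec_rows] = magnitude[spec_rows, None] * prof \
            * broad_noise[spec_rows]
    for tissue_idx, param, coeff in spec.tissue_links:
        z = features.latent[param].to_numpy()
        values[:, tissue_idx] = values[:, tissue_idx] * 2.0 ** (coeff * z)
    if spec.zero_inflation > 0:
        values[rng.random((n, t)) < spec.zero_inflation] = 0.0
    tissues = [f"tissue_{j:02d}" for j in range(t)]
    df = pd.DataFrame(values, index=features.table.index, columns=tissues)
    return ExpressionMatrix(values=df, is_normalized=False)


#: Stand-in generating coefficients for the height/legs toy example: leg
#: length = 0.5 * height + Gaussian noise with SD equal to 10% of the
#: height SD.  Strong but noisy dependence; the originally simulated
#: values are not published, so these defaults are illustrative.
TOY_DEFAULTS = dict(height_mean=170.0, height_sd=10.0, leg_coeff=0.5)


def generate_toy(case_id: str, n: int, seed: int, *,
                 height_mean: float | None = None,
                 height_sd: float | None = None,
                 leg_coeff: float | None = None,
                 noise_sd: float | None = None) -> pd.DataFrame:
    """Simulate the height/leg-length toy example.

    Case ``"a"``: both leg lengths are generated from height alone, so the
    legs are conditionally independent given height.  Case ``"b"``: the
    left leg is generated from height and the right leg from the left leg
    alone, so the right leg is conditionally independent of height given
    the left leg.  Simple correlations cannot tell the two cases apart;
    partial correlations can.
    """
    if case_id not in ("a", "b"):
        raise ValueError(f"unknown toy case {case_id!r}; expected 'a' or 'b'")
    if n < 10:
        raise ValueError("toy example requires n >= 10")
    hm = TOY_DEFAULTS["height_mean"] if height_mean is None else height_mean
    hs = TOY_DEFAULTS["height_sd"] if height_sd is None else height_sd
    beta = TOY_DEFAULTS["leg_coeff"] if leg_coeff is None else leg_coeff
    sigma = 0.1 * hs if noise_sd is None else noise_sd
    rng = np.random.default_rng([int(seed), 2])
    height = hm + hs * rng.standard_normal(n)
    left = beta * height + sigma * rng.standard_normal(n)
    if case_id == "a":
        right = beta * height + sigma * rng.standard_normal(n)
    else:
        right = left + sigma * rng.standard_normal(n)
    return pd.DataFrame({"height": height, "left_leg": left, "right_leg": right})
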