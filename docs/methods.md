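# Methods

## Partial Spearman correlation by residuals

For parameters a, b in a complete-case gene table with conditioning set Z
(all other active parameters), the reported statistic is the Spearman
correlation of the OLS residuals of a on [1, Z] and of b on [1, Z].
Ranks are mid-ranks (ties receive the mean of their positions)
throughout. With an empty Z the statistic reduces exactly to simple
Spearman correlation.

The two-sided p-value uses the t approximation
t = ρ·√(df/(1−ρ²)) with **df = n − 2**. The size of the conditioning set
is deliberately *not* subtracted: the statistic is literally "Spearman on
residuals", and its p-value is the one that computation produces. A
conservative variant with df = n − 2 − |Z| is available via
`df_correction=True`; at genome-scale n the difference is negligible.

Degenerate cases: a design whose cross-product matrix has reciprocal
condition number below 1e-10 raises a rank-deficiency error naming the
columns; a variable perfectly fit by Z (residual SD ≤ 1e-10 of the
variable's SD) yields an undefined (NaN) correlation with a warning
rather than rank noise.

## Significance tiers

Each network is one Benjamini–Hochberg family: the 78 pairs of a
13-parameter global run, or all (tissue × target) results of one
per-tissue run. Two independent tiers are assigned: `fdr1` if the
BH-adjusted p ≤ 0.01, `strong` if the raw p ≤ 0.0005. The edge-list
`tier` column reports the highest applicable label. Family boundaries
are per run; separate species or subsets form separate families.

## Expression pipeline

Raw linear-scale values are multiplied by 10⁶, exact zeros are replaced
by 1.0001, values are log₂-transformed, and columns are
quantile-normalized. The order is the only one in which the zero
replacement is well defined (log of zero otherwise); zeros thus
contribute log₂(1.0001) ≈ 1.44·10⁻⁴ before quantile normalization.

Quantile normalization maps each column's order statistics to the mean of
the corresponding order statistics across columns. Tied values within a
column receive the mean of the reference values of the ranks they span.
With massive ties (zero-inflated columns) this is the only stable choice,
but it trades away exact multiset identity across columns: tie averaging
replaces several distinct reference values by one shared value, so the
"identical multiset" postcondition holds exactly only for tie-free
columns. Column *means* are preserved exactly in all cases (averaging
within a group preserves its sum), and the tests check both facets.

τ is computed on the normalized log₂ profile with negative values floored
at zero, following the convention that the index takes non-negative
inputs; a gene with no positive value anywhere has undefined τ (NaN,
excluded by the complete-case filter). Median and maximal expression are
taken over all tissues, including replaced-zero values.

## Transformation ledger

Before correlation: ω₀, τ, intron length, intron number, CDS length and
paralog number are log₂-transformed, adding the column's minimal non-zero
value first when zeros are present; p₁ and ΔlnL take fourth roots;
GC content, stage number, phyletic age, essentiality, connectivity,
recombination rate, and all expression columns (already log₂ from the
pipeline) are left unchanged. All rules are strictly monotone, so simple
Spearman correlations are invariant to the ledger — used as a regression
test — while the OLS residual step is what the transforms actually
condition.

## Synthetic data

The generator is a pure function of its spec (including the seed).
Dependence is planted in a latent Gaussian layer: either a target
correlation matrix (Cholesky draw; non-positive-definite input is
rejected with the offending eigenvalue) or a causal DAG with linear
structural equations. Monotone marginal transforms then produce
realistic shapes — lognormal ω₀, uniform p₁, zero-inflated ΔlnL and
intron length, Poisson-like counts, ordinal ages — without disturbing
rank dependence except through the ties they deliberately introduce.

Closed-form oracles: for a bivariate Gaussian with correlation r the
population Spearman correlation is (6/π)·arcsin(r/2); pairwise partial
correlations implied by a correlation matrix follow from its inverse,
ρ<sub>ij·rest</sub> = −P<sub>ij</sub>/√(P<sub>ii</sub>P<sub>jj</sub>).
`planted_partial_spearman` composes the two, and recovery tests require
estimates within ±0.05 at n = 20 000.

Expression: each gene gets a log₂ magnitude (base N(3, 2²) on the log₂
FPKM-like scale, plus optional planted links to latent feature values,
globally or for single tissues). Broad genes receive near-uniform
profiles with log₂-scale noise (SD 0.25); tissue-specific genes place all
mass in one random dominant tissue (with an optional uniform leak,
default 0). Cells are independently zeroed with the stated dropout
probability. The defaults are chosen so that the broad/specific mixture
maps cleanly onto the τ < 0.2 / τ > 0.8 extremes after the normalization
pipeline; they emulate the *structure* of multi-tissue RNA-seq, not the
magnitudes or tissue identities of any real dataset — a green recovery
test establishes that the pipeline estimates the planted rank structure,
not that it would reproduce any particular organism's numbers.

Toy example: height ~ N(170, 10²); case (a) each leg = 0.5·height + ε,
case (b) left leg = 0.5·height + ε, right leg = left leg + ε, with
ε ~ N(0, 1) (10% of the height SD). The original simulation's
coefficients are not published; these stand-ins give the same qualitative
discrimination (all simple ρ > 0.8; case (a): legs conditionally
uncorrelated given height; case (b): right leg conditionally uncorrelated
with height given the left leg, legs' partial ρ ≈ 1/√2).

## Per-tissue analysis

For tissue t and target r ∈ {ω₀, p₁, ΔlnL}, the conditioning set is the
structural covariates plus the other two rate components. The global
expression parameters (τ, median, max) are excluded by default because
per-tissue expression is a component of all three; conditioning on them
would absorb the signal under study. The stricter alternative is a
config switch (`condition_on_global_expression=True`). The
tissue-specific subset rerun keeps genes with τ strictly above the
threshold (default 0.2) and errors below a minimum subset size
(default 50).

## Known limitations

- The t-approximation p-values are approximate in the extreme tail when
  variables carry very heavy ties (e.g. per-tissue expression among
  exclusively tissue-specific genes, where most entries are exact
  zeros). Borderline strong-tier edges with |ρ| near zero in such
  regimes should be treated with caution; the null-calibration tests
  quantify the behaviour for the default (broad-expression) regime.
- The residual step is a *linear* adjustment on transformed variables;
  strongly nonlinear confounding is only partially removed. This is
  intrinsic to the two-step definition.
- Variance explained is reported as the multiple-regression R² of the
  target on the predictors (transformed scale). Sums of squared partial
  correlations do not decompose variance and are not used.
- No batch correction, no microarray branch, and no fitting of the
  branch-site models themselves: ω₀, p₁ and ΔlnL are inputs.
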