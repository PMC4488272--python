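"""Per-tissue expression vs evolutionary-rate components.

A negative dependence between expression in tissue 0 and omega0 is planted;
everything else is conditionally null.  For each tissue and each rate
component (omega0, p1, delta_lnl) the pipeline computes the partial
Spearman correlation between that tissue's expression and the component,
conditioning on the structural covariates and the other two components.
The analysis is then repeated on the tissue-specific subset (tau > 0.2).
"""

import numpy as np

from ratecorr import (normalize_expression, run_per_tissue,
                      run_subset_specific, summarize_expression)
from ratecorr.simulate import SyntheticSpec, generate_expression, generate_features

MARGINALS = {
    "omega0": "lognormal", "p1": "uniform",
    "delta_lnl": "zero_inflate:0.3:exponential", "gc_content": "uniform",
    "intron_length": "zero_inflate:0.1:lognormal", "intron_number": "count:6",
    "cds_length": "lognormal", "paralog_number": "count:2",
    "phyletic_age": "ordinal:6", "stage_number": "ordinal:10",
}
PARAMS = tuple(MARGINALS)

spec = SyntheticSpec(params=PARAMS, n_genes=6000, seed=3,
                     latent_corr=np.eye(10), marginals=MARGINALS,
                     n_tissues=8, tissue_profile_mix=0.5,
                     tissue_links=((0, "omega0", -1.5),))
feats = generate_features(spec)
summ = summarize_expression(normalize_expression(generate_expression(spec, feats)))
features = feats.table.join(summ)

result = run_per_tissue(features)
print(f"{len(result.tissues)} tissues x {len(result.targets)} targets = "
      f"{len(result.edges)} partial correlations over {result.n_genes} genes")
print("\nstrong-tier edges (raw p <= 0.0005):")
print(result.edges[result.edges["tier"] == "strong"].to_string(index=False))

print("\nOn the full gene set only tissue 0 shows a strong omega0 edge, with")
print("the planted negative sign; the other 23 tissue-target pairs are")
print("conditionally null.")

subset = run_subset_specific(features)
print(f"\ntissue-specific subset (tau > 0.2): {subset.n_genes} genes")
sub_strong = subset.edges[subset.edges["tier"] == "strong"]
print(f"strong-tier edges in the subset: {len(sub_strong)}")
print(sub_strong.to_string(index=False))
print("\nIn the subset, per-tissue expression columns are dominated by exact")
print("zeros (specific genes express in one tissue only), so the t-based")
print("p-values are only approximate in the extreme tail: small-|rho| edges")
print("can drift across the 0.0005 cutoff. The generator plants this tie")
print("regime deliberately; interpret subset edges with |rho| near zero")
print("with caution.")
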