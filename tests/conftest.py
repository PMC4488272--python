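import numpy as np
import pandas as pd
import pytest

from ratecorr.io import ExpressionMatrix
from ratecorr.simulate import SyntheticSpec, generate_features

#: realistic marginal shapes for the 13-parameter core analysis set
CORE_MARGINALS = {
    "omega0": "lognormal",
    "p1": "uniform",
    "delta_lnl": "zero_inflate:0.3:exponential",
    "tau": "uniform",
    "median_expr": "normal",
    "max_expr": "normal",
    "gc_content": "uniform",
    "intron_length": "zero_inflate:0.1:lognormal",
    "intron_number": "count:6",
    "cds_length": "lognormal",
    "paralog_number": "count:2",
    "phyletic_age": "ordinal:6",
    "stage_number": "ordinal:10",
}
CORE_PARAM_TUPLE = tuple(CORE_MARGINALS)


@pytest.fixture
def small_expression():
    """3 genes x 2 tissues, linear scale, including a zero cell."""
    values = pd.DataFrame(
        [[1e-6, 2e-6], [3e-6, 4e-6], [0.0, 6e-6]],
        index=["gA", "gB", "gC"], columns=["liver", "brain"],
    )
    return ExpressionMatrix(values=values)


@pytest.fixture
def hand_expression():
    """The 3x2 fixture whose normalization is known by hand computation."""
    values = pd.DataFrame(
        {"t1": [1e-6, 3e-6, 5e-6], "t2": [2e-6, 4e-6, 6e-6]},
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(values=values)


@pytest.fixture
def core_features():
    """Null-structure synthetic feature table over the 13 core parameters."""
    spec = SyntheticSpec(params=CORE_PARAM_TUPLE, n_genes=400, seed=11,
                         latent_corr=np.eye(13), marginals=CORE_MARGINALS)
    return generate_features(spec).table


def corr_with(params, pairs):
    """Correlation matrix with the stated off-diagonal entries."""
    k = len(params)
    corr = np.eye(k)
    idx = {p: i for i, p in enumerate(params)}
    for a, b, r in pairs:
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr
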