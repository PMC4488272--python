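import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratecorr.correlation import (assign_tiers, partial_corr,
                                  partial_corr_network, partial_spearman,
                                  spearman, variance_explained)
from ratecorr.simulate import planted_partial_spearman

from _oracles import (oracle_partial_spearman, oracle_spearman,
                      oracle_spearman_d2)


@pytest.mark.parametrize("x,y,expected", [
    ([1, 2, 3], [1, 2, 3], 1.0),
    ([1, 2, 3], [3, 2, 1], -1.0),
    ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], 0.8),  # 1 - 6*4/120, d = (±1,±1,0)
], ids=["monotone", "reversal", "d2-formula"])
def test_spearman_known_values(x, y, expected):
    res = spearman(x, y)
    assert res.rho == pytest.approx(expected, abs=1e-12)
    assert res.rho == pytest.approx(oracle_spearman_d2(x, y), abs=1e-12)


def test_spearman_result_fields():
    res = spearman([1, 2, 3, 4], [1, 3, 2, 4], name_a="b", name_b="a")
    assert (res.param_a, res.param_b) == ("a", "b")  # canonical pair order
    assert res.n == 4
    assert res.conditioning_set == ()
    assert 0 <= res.p_value <= 1


def test_spearman_zero_variance_is_missing():
    with pytest.warns(RuntimeWarning, match="zero variance"):
        res = spearman([1.0, 1.0, 1.0], [1, 2, 3])
    assert np.isnan(res.rho) and np.isnan(res.p_value)


def test_spearman_requires_n3():
    with pytest.raises(ValueError, match="n >= 3"):
        spearman([1, 2], [1, 2])


def test_empty_conditioning_set_reduces_to_simple():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=50), rng.normal(size=50)
    assert partial_spearman(x, y).rho == spearman(x, y).rho
    assert partial_spearman(x, y).p_value == spearman(x, y).p_value


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_partial_spearman_matches_bruteforce_oracle(seed):
    """Residual-based partial Spearman equals an independently coded
    normal-equations + explicit-rank-formula oracle to 1e-10."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(50, 6))
    x, y, Z = data[:, 0], data[:, 1], data[:, 2:]
    res = partial_spearman(x, y, Z)
    assert res.rho == pytest.approx(oracle_partial_spearman(x, y, Z),
                                    abs=1e-10)


def test_partial_spearman_symmetry_and_invariance():
    rng = np.random.default_rng(3)
    x, y, Z = rng.normal(size=80), rng.normal(size=80), rng.normal(size=(80, 3))
    a = partial_spearman(x, y, Z).rho
    b = partial_spearman(y, x, Z).rho
    assert a == b
    # affine rescaling of x, y and any Z column leaves rho unchanged
    Z2 = Z.copy()
    Z2[:, 1] = -3.0 * Z2[:, 1] + 7.0
    c = partial_spearman(2.0 * x + 1.0, 0.5 * y - 4.0, Z2).rho
    assert c == pytest.approx(a, abs=1e-10)


def test_rank_deficient_design_rejected():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=30), rng.normal(size=30)
    z = rng.normal(size=30)
    Z = np.column_stack([z, 2.0 * z])  # collinear
    with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
        partial_spearman(x, y, Z, conditioning_names=("z1", "z2"))


def test_perfect_fit_gives_missing_with_warning():
    z = np.linspace(0, 1, 30)
    x = 2.0 * z + 1.0  # exactly explained by the conditioning set
    y = np.random.default_rng(0).normal(size=30)
    with pytest.warns(RuntimeWarning, match="zero variance"):
        res = partial_spearman(x, y, z[:, None])
    assert np.isnan(res.rho)


def test_df_correction_flag():
    rng = np.random.default_rng(2)
    x, y, Z = rng.normal(size=40), rng.normal(size=40), rng.normal(size=(40, 5))
    default = partial_spearman(x, y, Z)
    corrected = partial_spearman(x, y, Z, df_correction=True)
    assert default.rho == corrected.rho
    assert corrected.p_value > default.p_value  # fewer df, larger p


class TestNetwork:
    def test_pair_count_and_order(self, core_features):
        net = partial_corr_network(core_features, list(core_features.columns))
        k = core_features.shape[1]
        assert len(net.results) == k * (k - 1) // 2
        pairs = [(r.param_a, r.param_b) for r in net.results]
        assert pairs == sorted(pairs)
        for r in net.results:
            assert len(r.conditioning_set) == k - 2
            assert r.param_a not in r.conditioning_set
            assert r.param_b not in r.conditioning_set

    def test_row_permutation_invariance(self, core_features):
        params = list(core_features.columns)[:5]
        net1 = partial_corr_network(core_features, params)
        shuffled = core_features.sample(frac=1.0, random_state=9)
        net2 = partial_corr_network(shuffled, params)
        for r1, r2 in zip(net1.results, net2.results):
            assert r2.rho == pytest.approx(r1.rho, abs=1e-12)

    def test_requires_three_params(self, core_features):
        with pytest.raises(ValueError, match=">= 3"):
            partial_corr_network(core_features, ["omega0", "p1"])

    def test_planted_precision_structure_recovered(self, corr3=None):
        """k=3 Gaussian with known precision matrix: estimated partial
        correlations land within 0.05 of the closed-form values."""
        corr = np.array([[1.0, 0.5, 0.2],
                         [0.5, 1.0, -0.3],
                         [0.2, -0.3, 1.0]])
        rng = np.random.default_rng(42)
        data = rng.multivariate_normal(np.zeros(3), corr, size=20000)
        table = pd.DataFrame(data, columns=["a", "b", "c"])
        net = partial_corr_network(table)
        planted = planted_partial_spearman(corr)
        names = ["a", "b", "c"]
        for r in net.results:
            i, j = names.index(r.param_a), names.index(r.param_b)
            assert r.rho == pytest.approx(planted[i, j], abs=0.05)


class TestTiers:
    def test_bh_hand_computation(self):
        """p family [0.001, 0.02, 0.03, 0.8] -> BH-adjusted
        [0.004, 0.04, 0.04, 0.8]; first three pass at 5%."""
        from ratecorr.correlation import CorrelationNetwork, CorrelationResult
        ps = [0.001, 0.02, 0.03, 0.8]
        results = [CorrelationResult(f"a{i}", f"b{i}", 0.1, p, 100)
                   for i, p in enumerate(ps)]
        net = CorrelationNetwork(params=[], results=results)
        tiered = assign_tiers(net, fdr_alpha=0.05, strong_p=0.0005)
        assert [r.fdr1 for r in tiered.results] == [True, True, True, False]
        assert not any(r.strong for r in tiered.results)

    def test_all_ones_nothing_significant(self):
        from ratecorr.correlation import CorrelationNetwork, CorrelationResult
        results = [CorrelationResult(f"a{i}", f"b{i}", 0.0, 1.0, 50)
                   for i in range(5)]
        tiered = assign_tiers(CorrelationNetwork(params=[], results=results))
        assert all(r.tier == "not_significant" for r in tiered.results)

    def test_tier_labels_and_signs(self):
        from ratecorr.correlation import CorrelationNetwork, CorrelationResult
        results = [CorrelationResult("a", "b", -0.5, 1e-6, 100),
                   CorrelationResult("a", "c", 0.3, 0.002, 100),
                   CorrelationResult("b", "c", 0.01, 0.9, 100)]
        tiered = assign_tiers(CorrelationNetwork(params=["a", "b", "c"],
                                                 results=results))
        frame = tiered.to_edge_frame()
        assert list(frame["tier"]) == ["strong", "fdr1", "not_significant"]
        assert list(frame["sign"]) == ["-", "+", "+"]


class TestVarianceExplained:
    def test_saturated_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        y = X @ [1.0, -2.0, 0.5] + 3.0
        table = pd.DataFrame(np.column_stack([y, X]),
                             columns=["y", "x1", "x2", "x3"])
        assert variance_explained(table, "y", ["x1", "x2", "x3"]) == \
            pytest.approx(1.0, abs=1e-12)

    def test_independent_target_near_zero(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(20000, 4)),
                             columns=["y", "x1", "x2", "x3"])
        assert variance_explained(table, "y", ["x1", "x2", "x3"]) < 0.01

    def test_planted_r2_recovered(self):
        """y = b*x1 + e with Var(b*x1)/Var(y) = 0.5 -> R^2 = 0.5 +- 0.03."""
        rng = np.random.default_rng(2)
        n = 20000
        x1 = rng.normal(size=n)
        y = x1 + rng.normal(size=n)  # equal signal and noise variance
        table = pd.DataFrame({"y": y, "x1": x1, "x2": rng.normal(size=n)})
        r2 = variance_explained(table, "y", ["x1", "x2"])
        assert r2 == pytest.approx(0.5, abs=0.03)

    def test_target_among_predictors_rejected(self):
        table = pd.DataFrame({"y": [1., 2., 3.], "x": [1., 2., 4.]})
        with pytest.raises(ValueError, match="target"):
            variance_explained(table, "y", ["y", "x"])
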