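import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from microprot import (
    AbundanceMatrix,
    ValidationError,
    apply_size_factors,
    compute_nsaf,
    correlate_pairs,
    estimate_size_factors,
    johnson_transform,
)
from microprot.quantify import transform_matrix

from conftest import make_table


class TestNSAF:
    def test_single_protein_is_one(self):
        t = make_table(counts={"s1": [7]}, lengths={"A": 123})
        m = compute_nsaf(t)
        assert m.values.loc["A", "s1"] == pytest.approx(1.0)

    def test_hand_arithmetic_two_proteins(self):
        # counts (10, 10), lengths (100, 50): SAF (0.1, 0.2) -> NSAF (1/3, 2/3)
        t = make_table(counts={"s1": [10, 10]}, lengths={"A": 100, "B": 50})
        m = compute_nsaf(t)
        assert m.values["s1"].tolist() == pytest.approx([1 / 3, 2 / 3])

    def test_zeros_preserved(self, toy_table):
        m = compute_nsaf(toy_table)
        zero_counts = toy_table.counts.to_numpy() == 0
        assert ((m.values.to_numpy() == 0) == zero_counts).all()

    def test_all_zero_sample_errors_with_name(self):
        t = make_table(counts={"s1": [3], "bad": [0]}, lengths={"A": 10})
        with pytest.raises(ValidationError, match="bad"):
            compute_nsaf(t)

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_columns_sum_to_one(self, data):
        n = data.draw(st.integers(2, 8))
        counts = data.draw(
            st.lists(
                st.lists(st.integers(0, 50), min_size=n, max_size=n),
                min_size=2,
                max_size=4,
            )
        )
        lengths = data.draw(st.lists(st.integers(1, 500), min_size=n, max_size=n))
        cols = {f"s{j}": [row[i] for i in range(n)] for j, row in enumerate(counts)}
        if any(sum(c) == 0 for c in cols.values()):
            return
        t = make_table(counts=cols, lengths={f"P{i}": lengths[i] for i in range(n)})
        m = compute_nsaf(t)
        np.testing.assert_allclose(m.values.sum(axis=0), 1.0, atol=1e-9)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        vals = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        sf = estimate_size_factors(AbundanceMatrix(vals, stage="size_normalized"))
        np.testing.assert_allclose(sf.factors, 1.0)

    def test_doubled_column_hand_result(self):
        # column2 = 2 x column1: median of ratios gives (1/sqrt2, sqrt2)
        vals = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 6]})
        sf = estimate_size_factors(AbundanceMatrix(vals, stage="size_normalized"))
        np.testing.assert_allclose(sf.factors, [2**-0.5, 2**0.5])

    def test_single_sample_unit_factor(self):
        vals = pd.DataFrame({"a": [1.0, 2, 3]})
        sf = estimate_size_factors(AbundanceMatrix(vals, stage="size_normalized"))
        assert sf.factors["a"] == pytest.approx(1.0)

    def test_no_common_protein_errors(self):
        vals = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        with pytest.raises(ValidationError, match="pseudo-count"):
            estimate_size_factors(AbundanceMatrix(vals, stage="size_normalized"))

    def test_planted_factor_recovery(self, rng):
        # multiplying columns by known factors (geometric mean 1) is recovered
        base = rng.lognormal(0.0, 1.0, 600)
        f = np.array([0.7, 1.1, 1.4])
        f = f / np.exp(np.mean(np.log(f)))
        noise = rng.lognormal(0.0, 0.2, (600, 3))
        vals = pd.DataFrame(base[:, None] * f[None, :] * noise, columns=list("abc"))
        sf = estimate_size_factors(AbundanceMatrix(vals, stage="size_normalized"))
        np.testing.assert_allclose(sf.factors, f, rtol=0.05)

    def test_apply_divides_columns(self, toy_table):
        m = compute_nsaf(toy_table)
        sf = estimate_size_factors(m)
        norm = apply_size_factors(m, sf)
        assert norm.stage == "size_normalized"
        np.testing.assert_allclose(
            norm.values.to_numpy(), m.values.to_numpy() / sf.factors.to_numpy()
        )


class TestJohnson:
    def test_normal_sample_not_degraded(self, rng):
        x = rng.normal(size=200)
        y, fit = johnson_transform(x)
        assert stats.shapiro(y).statistic >= stats.shapiro(x).statistic - 1e-6

    def test_lognormal_becomes_normal(self, rng):
        x = rng.lognormal(0.0, 1.0, 200)
        assert stats.shapiro(x).pvalue < 0.05
        y, fit = johnson_transform(x)
        assert fit.shapiro_p > 0.05
        assert stats.shapiro(y).pvalue > 0.05

    def test_constant_vector_errors(self):
        with pytest.raises(ValidationError, match="constant"):
            johnson_transform(np.ones(50))

    def test_too_few_values_errors(self):
        with pytest.raises(ValidationError, match=">= 20"):
            johnson_transform(np.arange(10.0))

    def test_transform_strictly_monotone(self, rng):
        x = np.sort(rng.lognormal(0.0, 0.8, 200))
        y, fit = johnson_transform(x)
        assert np.all(np.diff(np.asarray(fit.transform(np.unique(x)))) > 0)

    def test_fit_parameters_valid(self, rng):
        x = rng.lognormal(0.0, 1.0, 200)
        _, fit = johnson_transform(x)
        assert fit.delta > 0 and fit.lam > 0
        assert fit.family in ("SB", "SL", "SU")
        lo, hi = fit.support
        assert lo < x.min() and x.max() < hi


class TestCorrelation:
    def test_self_pair_r_is_one(self):
        t = make_table(
            counts={"s1": [3, 9, 27, 81], "s2": [1, 1, 1, 1]},
            lengths={a: 100 for a in "ABCD"},
        )
        out = correlate_pairs(compute_nsaf(t), [("s1", "s1")])
        assert out.pairs.loc[0, "r"] == pytest.approx(1.0)

    def test_exact_linearity_small_support(self):
        # tiny support falls back to raw values; exact colinearity gives r = 1
        t = make_table(
            counts={"x": [1, 2, 3], "y": [2, 4, 6]},
            lengths={"A": 10, "B": 10, "C": 10},
        )
        m = compute_nsaf(t)
        out = correlate_pairs(m, [("x", "y")])
        assert out.pairs.loc[0, "r"] == pytest.approx(1.0)

    def test_low_support_pair_skipped_with_warning(self):
        t = make_table(counts={"x": [5, 0], "y": [0, 0]}, lengths={"A": 10, "B": 10})
        m = AbundanceMatrix(
            pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 0.0]}), stage="size_normalized"
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = correlate_pairs(m, [("x", "y")])
        assert out.pairs.empty

    def test_pearson_affine_invariance(self, rng):
        m = AbundanceMatrix(
            pd.DataFrame(rng.lognormal(0, 1, (100, 2)), columns=["a", "b"]),
            stage="transformed",
        )
        r1 = correlate_pairs(m, [("a", "b")]).pairs.loc[0, "r"]
        m2 = AbundanceMatrix(
            pd.DataFrame(
                {"a": 3.0 * m.values["a"] + 5.0, "b": -0.5 * m.values["b"] + 1.0}
            ),
            stage="transformed",
        )
        r2 = correlate_pairs(m2, [("a", "b")]).pairs.loc[0, "r"]
        assert abs(r1) == pytest.approx(abs(r2), abs=1e-12)

    def test_replicate_pair_matches_monte_carlo_mean(self):
        # shared abundance + independent NB noise: one realisation's r lies
        # within +-0.1 of the mean r over 200 regenerations
        def one_r(seed):
            g = np.random.default_rng(seed)
            mu = g.lognormal(2.0, 1.0, 200)
            counts = {
                "r1": g.negative_binomial(10, 10 / (10 + mu)),
                "r2": g.negative_binomial(10, 10 / (10 + mu)),
            }
            t = make_table(
                counts={k: v.tolist() for k, v in counts.items()},
                lengths={f"P{i}": 100 for i in range(200)},
            )
            out = correlate_pairs(compute_nsaf(t), [("r1", "r2")])
            return float(out.pairs.loc[0, "r"])

        rs = [one_r(s) for s in range(200)]
        assert abs(one_r(777) - float(np.mean(rs))) < 0.1

    def test_r_avg_is_mean_of_pairs(self, rng):
        vals = pd.DataFrame(rng.lognormal(0, 1, (80, 3)), columns=["a", "b", "c"])
        m = AbundanceMatrix(vals, stage="transformed")
        pairs = [("a", "b"), ("a", "c")]
        out = correlate_pairs(m, pairs, comparisons={"grp": pairs})
        assert out.r_avg["grp"] == pytest.approx(out.pairs["r"].mean())


def test_transform_matrix_stage_and_monotone(rng):
    vals = pd.DataFrame(rng.lognormal(0, 1, (100, 2)), columns=["a", "b"])
    vals.iloc[:5, 0] = 0.0
    m = AbundanceMatrix(vals, stage="size_normalized")
    out, fit = transform_matrix(m)
    assert out.stage == "transformed"
    # zeros map below every detected value
    assert out.values.iloc[:5, 0].max() <= out.values.iloc[5:, 0].min()
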