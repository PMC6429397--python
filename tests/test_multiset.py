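import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from microprot import (
    IntersectionSpec,
    ValidationError,
    combination_sweep,
    count_in_at_least,
    expected_intersection,
    intersection_pmf,
    intersection_test,
    summarize_family,
)
from microprot.multiset import display_fe


class TestPmf:
    def test_single_set_is_point_mass(self):
        pmf = intersection_pmf([4], 10)
        np.testing.assert_allclose(pmf, [0, 0, 0, 0, 1.0], atol=1e-15)

    def test_two_sets_hand_hypergeometric(self):
        # N=5, n=(2,2): P(k) = C(2,k) C(3,2-k) / C(5,2) = 3/10, 6/10, 1/10
        pmf = intersection_pmf([2, 2], 5)
        np.testing.assert_allclose(pmf, [0.3, 0.6, 0.1], atol=1e-12)

    def test_m2_matches_hypergeometric_exactly(self):
        for N, n1, n2 in [(20, 5, 8), (30, 12, 17), (25, 25, 10)]:
            pmf = intersection_pmf([n1, n2], N)
            ref = stats.hypergeom.pmf(np.arange(min(n1, n2) + 1), N, n1, n2)
            np.testing.assert_allclose(pmf, ref, atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_sums_to_one_and_mean_identity(self, data):
        N = data.draw(st.integers(1, 40))
        m = data.draw(st.integers(1, 4))
        n = tuple(data.draw(st.integers(0, N)) for _ in range(m))
        pmf = intersection_pmf(n, N)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        mean = float((np.arange(len(pmf)) * pmf).sum())
        expected = expected_intersection(n, N)
        assert mean == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_set_larger_than_background_errors(self):
        with pytest.raises(ValidationError):
            intersection_pmf([11], 10)

    def test_three_sets_against_set_sampling_oracle(self):
        # independent oracle: sample the sets themselves and count overlaps
        n, N, draws = (8, 10, 12), 20, 200_000
        g = np.random.default_rng(2024)
        hits = np.zeros(min(n) + 1, dtype=np.int64)
        for _ in range(10):
            chunk = draws // 10
            inter = np.ones((chunk, N), dtype=bool)
            for size in n:
                order = np.argsort(g.random((chunk, N)), axis=1)
                inter &= order < size
            counts = inter.sum(axis=1)
            hits += np.bincount(counts, minlength=min(n) + 1)[: min(n) + 1]
        freq = hits / draws
        pmf = intersection_pmf(n, N)
        se = np.sqrt(np.maximum(pmf * (1 - pmf), 1e-12) / draws)
        assert np.all(np.abs(freq - pmf) <= 3 * se + 1e-9)


class TestIntersectionTest:
    def test_hand_case(self):
        r = intersection_test(IntersectionSpec((2, 2), 5, 2))
        assert r.expected == pytest.approx(0.8)
        assert r.fold_enrichment == pytest.approx(2.5)
        assert r.p_value == pytest.approx(0.1)

    def test_observed_zero_gives_p_one(self):
        r = intersection_test(IntersectionSpec((3, 4), 12, 0))
        assert r.p_value == pytest.approx(1.0)

    def test_fe_near_one_at_expectation(self):
        n, N = (40, 50), 60
        e = expected_intersection(n, N)
        r = intersection_test(IntersectionSpec(n, N, round(e)))
        assert 0.9 <= r.fold_enrichment <= 1.1

    def test_p_monotone_in_observed(self):
        n, N = (10, 14, 9), 30
        ps = [intersection_test(IntersectionSpec(n, N, x)).p_value for x in range(10)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_observed_above_smallest_set_rejected(self):
        with pytest.raises(ValidationError):
            IntersectionSpec((3, 5), 10, 4)

    def test_floor_flagging_deep_tail(self):
        # large, almost-complete overlap of big sets drives p below the floor
        r = intersection_test(IntersectionSpec((1000, 1000, 1000), 16972, 1000))
        assert r.p_floored
        assert r.p_display == "< 1.0e-307"
        assert r.log_p < math.log(1e-307)


class TestSweep:
    def test_identical_sets_symmetric(self):
        s = set(range(10))
        res = combination_sweep({"a": s, "b": s, "c": s}, background=50)
        assert len(res) == 4  # 2^3 - 3 - 1
        by_order = {}
        for r in res:
            assert r.observed == 10
            by_order.setdefault(len(r.members), set()).add(round(r.fold_enrichment, 9))
        for fes in by_order.values():
            assert len(fes) == 1  # equal FE within an order

    def test_disjoint_sets_all_p_one(self):
        res = combination_sweep(
            {"a": {1, 2}, "b": {3, 4}, "c": {5, 6}}, background=100
        )
        assert all(r.observed == 0 and r.p_value == pytest.approx(1.0) for r in res)

    def test_sweep_consistent_with_direct_test(self, rng):
        names = list("abcd")
        sets = {nm: set(rng.choice(100, size=rng.integers(5, 30), replace=False))
                for nm in names}
        res = combination_sweep(sets, background=100)
        for r in res:
            direct = intersection_test(
                IntersectionSpec(r.set_sizes, 100, r.observed)
            )
            assert r.p_value == pytest.approx(direct.p_value)
            assert r.fold_enrichment == pytest.approx(direct.fold_enrichment)

    def test_union_background(self):
        res = combination_sweep({"a": {1, 2, 3}, "b": {3, 4}}, background="union")
        assert res[0].background_size == 4

    def test_too_many_sets_errors(self):
        with pytest.raises(ValidationError):
            combination_sweep({str(i): {i} for i in range(13)}, background=100)

    def test_family_summary_fisher(self, rng):
        sets = {nm: set(rng.choice(60, size=20, replace=False)) for nm in "abc"}
        res = combination_sweep(sets, background=60)
        fam = summarize_family(res, order=2)
        pair_fes = [r.fold_enrichment for r in res if len(r.members) == 2]
        assert fam.fe_avg == pytest.approx(np.mean(pair_fes))
        assert fam.method == "fisher"
        chi = -2 * sum(r.log_p for r in res if len(r.members) == 2)
        assert fam.combined_p == pytest.approx(float(stats.chi2.sf(chi, 6)))


def test_count_in_at_least():
    sets = [{"A", "B", "C"}, {"B", "C", "D"}, {"C"}]
    assert count_in_at_least(sets, 1) == 4
    assert count_in_at_least(sets, 2) == 2
    assert count_in_at_least(sets, 3) == 1


def test_display_rounding_convention():
    assert display_fe(278.4) == "278"
    assert display_fe(2.814) == "2.8"
    assert display_fe(float("inf")) == "inf"
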