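import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microprot import (
    AnnotationTerm,
    ValidationError,
    contingency_enrichment,
    localization_profile,
    protrusion_term_percentage,
    term_enrichment,
)


class TestContingency:
    def test_published_protrusion_localization_numbers(self):
        # 118 of 904 identified proteins protrusion-localized vs 560 of the
        # 12,073-protein imaging atlas: FE 2.8, and the exclusive list 19/87
        # gives FE 4.7
        r = contingency_enrichment(118, 904, 560, 12073)
        assert round(r.fold_enrichment, 1) == 2.8
        assert round(r.pct_sample, 1) == 13.1
        assert round(r.pct_background, 1) == 4.6
        r2 = contingency_enrichment(19, 87, 560, 12073)
        assert round(r2.fold_enrichment, 1) == 4.7
        assert round(r2.pct_sample, 1) == 21.8

    def test_published_chi_square_p_values(self):
        # the printed significances correspond to Pearson chi-square on the
        # sample-vs-whole-background table
        r = contingency_enrichment(118, 904, 560, 12073)
        assert r.p_pearson == pytest.approx(5.54e-28, rel=0.01)
        r2 = contingency_enrichment(19, 87, 560, 12073)
        assert r2.p_pearson == pytest.approx(6.05e-14, rel=0.01)

    def test_null_case_exclusive_balanced(self):
        r = contingency_enrichment(10, 100, 50, 500, background_mode="exclusive")
        assert r.fold_enrichment == pytest.approx(1.0)
        assert r.chi2_pearson == pytest.approx(0.0, abs=1e-12)

    def test_hand_chi_square(self):
        # independent arithmetic oracle for (20, 50, 100, 1000)
        a, n_s, b, N_b = 20, 50, 100, 1000
        table = np.array([[a, n_s - a], [b, N_b - b]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi_hand = ((table - expected) ** 2 / expected).sum()
        r = contingency_enrichment(a, n_s, b, N_b)
        assert r.chi2_pearson == pytest.approx(chi_hand)

    def test_zero_background_hits_flags_infinite_fe(self):
        r = contingency_enrichment(5, 50, 0, 500, background_mode="exclusive")
        assert np.isinf(r.fold_enrichment)
        assert 0 <= r.p_pearson <= 1

    def test_swap_inverts_fe(self):
        r = contingency_enrichment(30, 200, 90, 1000)
        r_swapped = contingency_enrichment(90, 1000, 30, 200, "exclusive")
        assert r_swapped.fold_enrichment == pytest.approx(1 / r.fold_enrichment)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_yates_never_exceeds_pearson(self, data):
        n_s = data.draw(st.integers(1, 200))
        a = data.draw(st.integers(0, n_s))
        N_b = data.draw(st.integers(n_s, 2000))
        b = data.draw(st.integers(a, N_b))
        r = contingency_enrichment(a, n_s, b, N_b)
        assert r.chi2_yates <= r.chi2_pearson + 1e-12
        assert r.p_yates >= r.p_pearson - 1e-12

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            contingency_enrichment(10, 5, 20, 100)
        with pytest.raises(ValidationError):
            contingency_enrichment(10, 50, 5, 100)  # inclusive: b must cover a


def _terms(spec):
    return [
        AnnotationTerm(term_id=t, members=frozenset(m), is_protrusion_related=f)
        for t, m, f in spec
    ]


class TestTermEnrichment:
    def test_sample_equals_background_fe_one(self):
        bg = {f"g{i}" for i in range(20)}
        terms = _terms([("T1", {"g0", "g1"}, False), ("T2", {"g5"}, False)])
        df = term_enrichment(bg, bg, terms)
        np.testing.assert_allclose(df["fold_enrichment"], 1.0)

    def test_term_equal_to_sample_is_maximal(self):
        bg = {f"g{i}" for i in range(40)}
        sample = {"g0", "g1", "g2", "g3"}
        terms = _terms(
            [("EXACT", sample, False), ("HALF", {"g0", "g1", "g10", "g11"}, False)]
        )
        df = term_enrichment(sample, bg, terms).set_index("term_id")
        assert df.loc["EXACT", "fold_enrichment"] >= df.loc["HALF", "fold_enrichment"]

    def test_planted_enriched_term_ranks_first(self, rng):
        bg = {f"g{i}" for i in range(200)}
        sample = {f"g{i}" for i in range(20)}
        planted = ("PLANTED", set(sample), True)
        decoys = [
            (f"D{j}", set(rng.choice(sorted(bg), size=15, replace=False)), False)
            for j in range(30)
        ]
        df = term_enrichment(sample, bg, _terms([planted] + decoys))
        assert df.iloc[0]["term_id"] == "PLANTED"

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError):
            term_enrichment(set(), {"g1"}, _terms([("T", {"g1"}, False)]))

    def test_bh_column_present_and_bounded(self, rng):
        bg = {f"g{i}" for i in range(100)}
        sample = {f"g{i}" for i in range(10)}
        terms = _terms(
            [(f"T{j}", set(rng.choice(sorted(bg), size=10, replace=False)), False)
             for j in range(20)]
        )
        df = term_enrichment(sample, bg, terms)
        assert ((df["p_bh"] >= df["p_pearson"] - 1e-12) & (df["p_bh"] <= 1)).all()


class TestProtrusionPercentage:
    def test_none_flagged_gives_zero(self):
        import pandas as pd

        df = pd.DataFrame({"is_protrusion_related": [False] * 10})
        assert protrusion_term_percentage(df, 10) == 0.0

    def test_all_flagged_gives_hundred(self):
        import pandas as pd

        df = pd.DataFrame({"is_protrusion_related": [True] * 5})
        assert protrusion_term_percentage(df, 5) == 100.0

    def test_top_k_bounds(self):
        import pandas as pd

        df = pd.DataFrame({"is_protrusion_related": [True, False]})
        assert protrusion_term_percentage(df, 2) == 50.0
        with pytest.raises(ValidationError):
            protrusion_term_percentage(df, 3)


class TestLocalizationProfile:
    def test_sample_equals_control_no_enrichment(self):
        s = {f"g{i}" for i in range(30)}
        terms = _terms([("nucleus", {f"g{i}" for i in range(10)}, False)])
        df = localization_profile(s, s, terms)
        assert df.loc[0, "fold_enrichment"] == pytest.approx(1.0)
        assert df.loc[0, "direction"] == "none"

    def test_planted_nuclear_depletion_flagged(self, rng):
        control = {f"g{i}" for i in range(200)}
        nuclear = {f"g{i}" for i in range(80)}
        # protrusion-style sample avoids nuclear proteins
        sample = {f"g{i}" for i in range(100, 150)}
        terms = _terms([("nucleus", nuclear, False), ("membrane", sample, False)])
        df = localization_profile(sample, control, terms).set_index("compartment")
        assert df.loc["nucleus", "direction"] == "depleted"
        assert df.loc["membrane", "direction"] == "enriched"

    def test_single_compartment_single_row(self):
        terms = _terms([("pm", {"g1", "g2"}, False)])
        df = localization_profile({"g1"}, {"g1", "g2", "g3"}, terms)
        assert len(df) == 1

    def test_absent_compartment_skipped_with_warning(self):
        terms = _terms([("ghost", {"zz"}, False)])
        with pytest.warns(UserWarning, match="skipped"):
            df = localization_profile({"g1"}, {"g1", "g2"}, terms)
        assert df.empty
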