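"""Standard curves, absolute quantification, Welch tests and letters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aomlab.qpcr import (
    DegenerateVarianceError,
    ExtrapolationWarning,
    StandardPoint,
    CladeQuant,
    fit_standard_curve,
    fold_change,
    holm_adjust,
    letter_groups,
    quantify,
    welch_t,
)


def dilution_series(slope, intercept, decades=range(-2, 6)):
    return [
        StandardPoint(10.0**d, intercept + slope * d) for d in decades
    ]


class TestStandardCurve:
    def test_perfect_doubling_slope_gives_full_efficiency(self):
        curve = fit_standard_curve(dilution_series(-3.3219, 38.0))
        assert curve.efficiency == pytest.approx(1.0, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0)

    def test_slope_36_efficiency(self):
        curve = fit_standard_curve(dilution_series(-3.6, 38.0))
        assert curve.efficiency == pytest.approx(0.896, abs=0.001)

    def test_too_few_levels_rejected(self):
        points = [StandardPoint(10.0, 30.0), StandardPoint(100.0, 27.0)]
        with pytest.raises(ValueError, match="dilution"):
            fit_standard_curve(points)

    def test_rising_cq_with_copies_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve(dilution_series(+3.3, 20.0))


class TestQuantify:
    def setup_method(self):
        self.curve = fit_standard_curve(dilution_series(-3.3219, 38.0))

    def test_round_trip_on_a_standard(self):
        top = StandardPoint(1e5, 38.0 - 3.3219 * 5)
        quant = quantify(top.cq, self.curve, template_ng=5.0)
        copies_rxn = quant.copies_per_ng_dna * 5.0
        assert copies_rxn == pytest.approx(top.copies_per_ul, rel=1e-9)

    def test_one_cycle_earlier_doubles_copies(self):
        q1 = quantify(30.0, self.curve)
        q2 = quantify(29.0, self.curve)
        assert q2.copies_per_g_wet / q1.copies_per_g_wet == pytest.approx(
            2.0, rel=1e-3
        )

    def test_extrapolation_warns_not_errors(self):
        with pytest.warns(ExtrapolationWarning):
            quant = quantify(10.0, self.curve)
        assert quant.copies_per_g_wet > 0

    def test_bad_masses_rejected(self):
        with pytest.raises(ValueError):
            quantify(30.0, self.curve, sample_g_wet=0.0)


class TestFoldChange:
    def q(self, copies, day):
        return CladeQuant("ANME1", "b1", day, copies, copies / 500.0)

    @pytest.mark.parametrize(
        "final, initial, ratio, growth",
        [(3e5, 1e5, 3.0, True), (1e5, 1e5, 1.0, False), (5e4, 1e5, 0.5, False)],
    )
    def test_ratio_and_growth_call(self, final, initial, ratio, growth):
        fc = fold_change(self.q(final, 344), self.q(initial, 0))
        assert fc.ratio == pytest.approx(ratio)
        assert fc.growth is growth

    def test_zero_initial_rejected(self):
        with pytest.raises(ValueError, match="zero initial"):
            fold_change(self.q(1e5, 344), self.q(0.0, 0))

    def test_clade_mismatch_rejected(self):
        other = CladeQuant("ANME2c", "b1", 0, 1e5, 200.0)
        with pytest.raises(ValueError):
            fold_change(self.q(1e5, 344), other)


class TestWelch:
    def test_identical_triplicates(self):
        t, df, p = welch_t([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        t, df, p = welch_t([10, 12, 14], [20, 22, 24])
        assert t == pytest.approx(-6.124, abs=0.01)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0036, abs=0.0005)

    def test_swap_flips_sign_keeps_p(self):
        a, b = [1.0, 2.0, 4.0], [5.0, 6.0, 9.0]
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t2 == pytest.approx(-t1)
        assert df2 == pytest.approx(df1)
        assert p2 == pytest.approx(p1)

    def test_degenerate_zero_variance_equal_means(self):
        t, df, p = welch_t([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_zero_variance_unequal_means(self):
        with pytest.raises(DegenerateVarianceError):
            welch_t([2.0, 2.0], [3.0, 3.0])

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_scipy_unequal_variance(self, data):
        from scipy import stats

        vals = st.floats(-50, 50)
        a = data.draw(st.lists(vals, min_size=2, max_size=8))
        b = data.draw(st.lists(vals, min_size=2, max_size=8))
        a, b = np.asarray(a), np.asarray(b)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            return
        t, df, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10, abs=1e-10)
        assert df == pytest.approx(ref.df, rel=1e-10, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10, abs=1e-10)


def pmatrix(n, significant_pairs, low=0.001, high=0.8):
    p = np.full((n, n), high)
    np.fill_diagonal(p, 1.0)
    for i, j in significant_pairs:
        p[i, j] = p[j, i] = low
    return p


class TestLetterGroups:
    def test_all_similar_share_one_letter(self):
        assert letter_groups(pmatrix(4, [])) == ["a", "a", "a", "a"]

    def test_two_blocks(self):
        p = pmatrix(4, [(0, 2), (0, 3), (1, 2), (1, 3)])
        assert letter_groups(p) == ["a", "a", "b", "b"]

    def test_three_node_chain(self):
        # 0 and 2 differ; 1 is compatible with both
        assert letter_groups(pmatrix(3, [(0, 2)])) == ["a", "ab", "b"]

    def test_invariant_to_p_relabeling_above_alpha(self):
        p1 = pmatrix(4, [(0, 3)], high=0.06)
        p2 = pmatrix(4, [(0, 3)], high=0.99)
        assert letter_groups(p1, alpha=0.05) == letter_groups(p2, alpha=0.05)

    def test_asymmetric_matrix_rejected(self):
        p = pmatrix(3, [])
        p[0, 1] = 0.01
        with pytest.raises(ValueError, match="symmetric"):
            letter_groups(p)


def test_holm_adjustment_is_monotone_and_bounded():
    p = [0.001, 0.04, 0.03, 0.9]
    adj = holm_adjust(p)
    assert np.all(adj >= np.asarray(p))
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
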