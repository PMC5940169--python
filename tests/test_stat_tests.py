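"""Proportion, Welch and Wald tests, checked against independent formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ohnoretain import (
    BaselineRange,
    DegenerateTableError,
    SeparationError,
    one_sample_prop_vs_baseline,
    two_sample_prop_test,
    wald_group_effect,
    welch_t_test,
)


def _pearson_chi2_oracle(k1, n1, k2, n2):
    """Textbook observed-vs-expected chi-square, independent of the closed form."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - expected) ** 2 / expected).sum())


class TestTwoSampleProp:
    def test_identical_tables_give_zero_statistic(self):
        res = two_sample_prop_test((30, 100), (30, 100), continuity_correction=False)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_uncorrected_matches_observed_expected_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n1, n2 = rng.integers(2, 80, size=2)
            k1 = int(rng.integers(1, n1))
            k2 = int(rng.integers(1, n2))
            res = two_sample_prop_test((k1, n1), (k2, n2), continuity_correction=False)
            assert res.statistic == pytest.approx(
                _pearson_chi2_oracle(k1, n1, k2, n2), rel=1e-10
            )
            scipy_stat, scipy_p, _, _ = stats.chi2_contingency(
                [[k1, n1 - k1], [k2, n2 - k2]], correction=False
            )[:4]
            assert res.statistic == pytest.approx(scipy_stat, rel=1e-10)
            assert res.p_value == pytest.approx(scipy_p, rel=1e-10)

    def test_monogenic_vs_multigenic_teleost_split(self):
        res = two_sample_prop_test((50, 107), (13, 77), continuity_correction=False)
        assert res.p_value == pytest.approx(2.6e-5, rel=0.1)
        assert res.method == "pearson_chi2"

    def test_salmonid_round_comparisons_need_correction_to_match(self):
        assert two_sample_prop_test((112, 153), (65, 90)).p_value == pytest.approx(
            0.98, abs=0.01
        )
        assert two_sample_prop_test((86, 119), (91, 124)).p_value == pytest.approx(
            0.96, abs=0.01
        )

    def test_zero_marginal_recommends_exact_test(self):
        with pytest.raises(DegenerateTableError, match="exact test"):
            two_sample_prop_test((0, 10), (0, 15))

    @settings(max_examples=200, deadline=None)
    @given(
        k1=st.integers(0, 50), m1=st.integers(0, 50),
        k2=st.integers(0, 50), m2=st.integers(0, 50),
    )
    def test_yates_p_never_below_pearson_and_swap_invariant(self, k1, m1, k2, m2):
        n1, n2 = k1 + m1, k2 + m2
        if 0 in (n1, n2, k1 + k2, m1 + m2):
            return
        plain = two_sample_prop_test((k1, n1), (k2, n2), continuity_correction=False)
        yates = two_sample_prop_test((k1, n1), (k2, n2), continuity_correction=True)
        assert yates.p_value >= plain.p_value - 1e-12
        # row swap
        swapped = two_sample_prop_test((k2, n2), (k1, n1), continuity_correction=False)
        assert swapped.statistic == pytest.approx(plain.statistic, abs=1e-12)
        # column swap (retained <-> lost)
        cols = two_sample_prop_test((m1, n1), (m2, n2), continuity_correction=False)
        assert cols.statistic == pytest.approx(plain.statistic, abs=1e-12)


class TestOneSampleProp:
    def test_teleost_overall_vs_upper_baseline_bound(self):
        res = one_sample_prop_vs_baseline((63, 184), BaselineRange("TSGD", 0.04, 0.18))
        assert res.inputs["p0"] == 0.18
        assert res.p_value < 1e-7

    def test_salmonid_overall_magnitude(self):
        res = one_sample_prop_vs_baseline((182, 242), BaselineRange("SSGD", 0.48, 0.55))
        assert -11 < math.log10(res.p_value) < -9

    def test_rate_equal_to_bound_gives_p_one(self):
        res = one_sample_prop_vs_baseline((18, 100), BaselineRange("TSGD", 0.04, 0.18))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_within_range_is_nonsignificant_by_construction(self):
        res = one_sample_prop_vs_baseline((10, 100), BaselineRange("TSGD", 0.04, 0.18))
        assert res.inputs["within_baseline_range"] is True and res.p_value == 1.0

    def test_statistic_matches_score_formula(self):
        k, n, p0 = 63, 184, 0.18
        res = one_sample_prop_vs_baseline((k, n), BaselineRange("TSGD", 0.04, p0))
        z = (k / n - p0) / math.sqrt(p0 * (1 - p0) / n)
        assert res.statistic == pytest.approx(z**2, rel=1e-12)

    def test_degenerate_baseline_contradicted_by_data(self):
        with pytest.raises(DegenerateTableError, match="degenerate"):
            one_sample_prop_vs_baseline((5, 10), BaselineRange("TSGD", 0.0, 0.0))


class TestWelch:
    def test_identical_samples_give_zero_statistic(self):
        res = welch_t_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_large_shift_dominates(self):
        res = welch_t_test([1, 2, 3, 4], [11, 12, 13, 14])
        assert res.p_value < 0.001

    def test_matches_textbook_formula(self):
        x = np.array([5.1, 6.2, 4.8, 7.0, 5.5])
        y = np.array([2.0, 2.4, 1.9, 2.6])
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        res = welch_t_test(x, y)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.df == pytest.approx(df, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="two values"):
            welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            welch_t_test([3.0, 3.0], [5.0, 5.0])


class TestWaldGroupEffect:
    def test_identical_groups_give_null_result(self):
        y = [1] * 30 + [0] * 70 + [1] * 30 + [0] * 70
        g = ["a"] * 100 + ["b"] * 100
        res = wald_group_effect(y, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_two_groups_asymptotically_match_pearson_chi2(self):
        rng = np.random.default_rng(99)
        n = 600
        ya = rng.random(n) < 0.40
        yb = rng.random(n) < 0.50
        res = wald_group_effect(
            np.concatenate([ya, yb]).astype(int), ["a"] * n + ["b"] * n
        )
        chi2 = two_sample_prop_test(
            (int(ya.sum()), n), (int(yb.sum()), n), continuity_correction=False
        )
        assert res.statistic == pytest.approx(chi2.statistic, rel=0.10)
        assert res.df == 1

    def test_planted_five_group_effect_detected(self):
        rng = np.random.default_rng(2018)
        logits = [0.0, 0.0, 0.0, 0.0, 2.0]
        y, g = [], []
        for i, lo in enumerate(logits):
            p = 1 / (1 + math.exp(-lo + 0.5))
            y += list((rng.random(200) < p).astype(int))
            g += [f"cat{i}"] * 200
        res = wald_group_effect(y, g)
        assert res.df == 4 and res.p_value < 0.01
        assert res.inputs["lrt_p_value"] < 0.01

    def test_complete_separation_names_group(self):
        y = [1] * 20 + [1, 0] * 10
        g = ["all_kept"] * 20 + ["mixed"] * 20
        with pytest.raises(SeparationError, match="all_kept"):
            wald_group_effect(y, g)
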