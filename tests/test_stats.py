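"""Agreement and association statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epifat import (bland_altman, bsa, icc, interpret_icc, paired_compare,
                    percent_error, regress_bmi)
from epifat.stats import agreement_analysis, pair_measurements


# ---------------------------------------------------------------------------
# independent oracles

def icc_anova_oracle(vals: np.ndarray, model: str = "icc2") -> float:
    """Brute-force two-way ANOVA mean squares -> single-measures ICC."""
    vals = np.asarray(vals, float)
    n, k = vals.shape
    grand = vals.mean()
    ms_rows = k * ((vals.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((vals.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ss_tot = ((vals - grand) ** 2).sum()
    ms_err = (ss_tot - ms_rows * (n - 1) - ms_cols * (k - 1)) \
        / ((n - 1) * (k - 1))
    if model == "icc2":
        return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err
                                     + k * (ms_cols - ms_err) / n)
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def signed_rank_enumeration(diff: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors
    (tie-free differences)."""
    ranks = sps.rankdata(np.abs(diff))
    t_obs = ranks[diff > 0].sum()
    dist = np.array([sum(r for s, r in zip(signs, ranks) if s)
                     for signs in itertools.product([0, 1], repeat=len(diff))])
    p = 2 * min((dist <= t_obs).mean(), (dist >= t_obs).mean())
    return min(1.0, p)


def ols_closed_form(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ss_res = (resid ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se
    p = 2 * sps.t.sf(abs(t), n - 2)
    return slope, intercept, r2, p


# ---------------------------------------------------------------------------

class TestBlandAltman:
    def test_identical_measurements(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_diff_ml == 0.0 and r.sd_diff_ml == 0.0
        assert r.loa_low == r.loa_high == 0.0

    def test_constant_offset(self):
        x = np.array([4.0, 5.0, 6.0])
        r = bland_altman(x, x - 2.5)
        assert r.mean_diff_ml == pytest.approx(2.5)
        assert r.sd_diff_ml == 0.0
        assert (r.loa_low, r.loa_high) == (pytest.approx(2.5),
                                           pytest.approx(2.5))

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 4.0, 4.0])
        r = bland_altman(x, y)
        # diffs [0, 1, -1, 0]: mean 0, sample sd sqrt(2/3)
        assert r.mean_diff_ml == pytest.approx(0.0)
        assert r.sd_diff_ml == pytest.approx(np.sqrt(2.0 / 3.0))
        assert r.loa_high == pytest.approx(1.96 * np.sqrt(2.0 / 3.0))
        assert r.n_pairs == 4

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 20))
        fwd, rev = bland_altman(x, y), bland_altman(y, x)
        assert fwd.mean_diff_ml == pytest.approx(-rev.mean_diff_ml)
        assert fwd.sd_diff_ml == pytest.approx(rev.sd_diff_ml)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPercentError:
    @pytest.mark.parametrize("diff, total, expect", [
        (0.39, 165.0, 100 * 0.39 / 165.0),  # about 0.236 %
        (0.0, 50.0, 0.0),
        (1.0, 100.0, 1.0),
    ])
    def test_arithmetic(self, diff, total, expect):
        out = percent_error([diff], [total])
        assert out[0] == pytest.approx(expect)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent_error([1.0], [0.0])


class TestICC:
    def test_perfect_agreement(self):
        vals = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc(vals) == 1.0

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(200, 2))  # no between-target variance
        assert abs(icc(vals)) < 0.2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_anova_mean_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 2, size=6)
        vals = np.column_stack([base + rng.normal(0, 0.7, 6),
                                base + rng.normal(0, 0.7, 6) + 0.3])
        for model in ("icc2", "icc3"):
            assert icc(vals, model=model) == pytest.approx(
                icc_anova_oracle(vals, model), abs=1e-10)

    def test_toy_table_against_oracle(self):
        vals = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 8], [2, 4]],
                        float)
        assert icc(vals) == pytest.approx(icc_anova_oracle(vals), abs=1e-10)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 2, size=(12, 2))
        ref = icc(vals)
        assert icc(vals + 100.0) == pytest.approx(ref, abs=1e-9)
        assert icc(vals * 7.5) == pytest.approx(ref, abs=1e-9)

    def test_degenerate_constant_table_is_one_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            assert icc(np.full((5, 2), 3.0)) == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc(np.zeros((2, 2)))  # too few rows
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2, 2], [3, 3]]))


class TestInterpretICC:
    @pytest.mark.parametrize("value, label", [
        (0.96, "excellent"),
        (0.92, "excellent"),
        (0.76, "good"),
        (0.63, "moderate"),
        (0.49, "poor"),
        (0.5, "moderate"),   # boundary: upper class wins
        (0.75, "good"),
        (0.9, "excellent"),
        (-0.2, "poor"),
    ])
    def test_categories(self, value, label):
        assert interpret_icc(value) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            interpret_icc(1.5)


class TestBSA:
    def test_mosteller_closed_form(self):
        assert bsa(180.0, 72.0) == pytest.approx(np.sqrt(3.6))
        assert bsa(180.0, 20.0) == pytest.approx(1.0)
        assert bsa(160.0, 90.0) == pytest.approx(2.0)

    def test_dubois_alternative(self):
        expect = 0.007184 * 180 ** 0.725 * 72 ** 0.425
        assert bsa(180.0, 72.0, formula="dubois") == pytest.approx(expect)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            bsa(0.0, 72.0)


class TestRegressBMI:
    def test_exact_line(self):
        x = np.array([20.0, 24, 28, 32, 36])
        r = regress_bmi(2 * x, x)
        assert r.slope == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_response_has_zero_r2(self):
        r = regress_bmi([5.0, 5.0, 5.0, 5.0], [20.0, 25, 30, 35])
        assert r.r_squared == pytest.approx(0.0)
        assert r.slope == pytest.approx(0.0)

    def test_five_point_closed_form_oracle(self):
        bmi = np.array([21.0, 24.5, 27.0, 30.5, 39.0])
        fat = np.array([55.0, 61.0, 80.0, 70.0, 95.0])
        r = regress_bmi(fat, bmi)
        slope, intercept, r2, p = ols_closed_form(bmi, fat)
        assert r.slope == pytest.approx(slope)
        assert r.intercept == pytest.approx(intercept)
        assert r.r_squared == pytest.approx(r2)
        assert r.p_value == pytest.approx(p)

    def test_constant_bmi_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_bmi([1.0, 2.0, 3.0], [25.0, 25.0, 25.0])


class TestPairedCompare:
    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 15)
        for kind in ("t", "wilcoxon"):
            r = paired_compare(a + 50.0, a, kind=kind)
            assert r.significant and r.p_value < 0.05

    def test_identical_pairs_t_test_convention(self):
        r = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="t")
        assert r.p_value == 1.0 and not r.significant

    def test_wilcoxon_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            paired_compare([1.0, 2.0], [1.0, 2.0], kind="wilcoxon")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_wilcoxon_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        # tie-free differences, n <= 10 -> scipy uses the exact method
        diff = rng.normal(0.3, 1.0, 9)
        diff += np.arange(9) * 1e-6  # break accidental |diff| ties
        a = np.zeros(9) + diff
        b = np.zeros(9)
        r = paired_compare(a, b, kind="wilcoxon")
        assert r.p_value == pytest.approx(signed_rank_enumeration(diff),
                                          abs=1e-12)


class TestObserverTablePlumbing:
    @staticmethod
    def _table():
        rows = []
        rng = np.random.default_rng(5)
        for pat in range(3):
            for z in (0, 10, 20):
                base = rng.uniform(1, 3)
                for obs in (1, 2):
                    for rep in (1, 2):
                        rows.append((pat, "cine", obs, rep, z,
                                     base + 0.05 * obs + 0.01 * rep))
        return pd.DataFrame(rows, columns=["patient", "method", "observer",
                                           "repeat", "slice", "volume_ml"])

    def test_intra_pairs_first_observer_repeats(self):
        pairs = pair_measurements(self._table(), "cine", "intra")
        assert len(pairs) == 9
        np.testing.assert_allclose(pairs["first"] - pairs["second"], -0.01)

    def test_inter_pairs_first_repeat_observers(self):
        pairs = pair_measurements(self._table(), "cine", "inter")
        np.testing.assert_allclose(pairs["first"] - pairs["second"], -0.05)

    def test_agreement_analysis_is_complete(self):
        res = agreement_analysis(self._table(), "cine", "inter")
        assert res.mean_diff_ml == pytest.approx(-0.05)
        assert res.icc is not None and res.icc_category is not None
        assert res.mean_diff_pct is not None
        assert res.n_pairs == 9

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            pair_measurements(pd.DataFrame({"patient": [1]}), "cine", "intra")
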