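"""IGF1 trajectory statistic and the group-comparison tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ropscreen as rs
from ropscreen.cohort import COHORT_COLUMNS


class TestPctIncrease:
    @pytest.mark.parametrize("w3,w5,expected", [
        (30.0, 30.0, 0.0),
        (40.0, 50.0, 25.0),
        (50.0, 40.0, -20.0),
    ])
    def test_examples(self, w3, w5, expected):
        assert rs.pct_increase(w3, w5) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        w3=st.floats(0.5, 200.0),
        w5=st.floats(0.5, 200.0),
        k=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, w3, w5, k):
        assert rs.pct_increase(k * w3, k * w5) == pytest.approx(
            rs.pct_increase(w3, w5), rel=1e-9, abs=1e-9
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rs.pct_increase(0.0, 10.0)
        with pytest.raises(ValueError):
            rs.pct_increase(10.0, -1.0)


def _cohort_from_deltas(deltas_by_grade: dict[str, list[float | None]]) -> rs.Cohort:
    rows = []
    i = 0
    for grade, deltas in deltas_by_grade.items():
        for d in deltas:
            rows.append({
                "infant_id": f"i{i}", "ga_weeks": 31.0, "birth_weight_g": 1400.0,
                "length_cm": None, "head_circ_cm": None,
                "igf1_w3": 40.0,
                "igf1_w5": None if d is None else 40.0 * (1 + d / 100.0),
                "sepsis_w3": 0, "rop_grade": grade,
            })
            i += 1
    return rs.Cohort(frame=pd.DataFrame(rows, columns=COHORT_COLUMNS))


class TestSummarizeByGrade:
    def test_identical_deltas_have_zero_width(self):
        cohort = _cohort_from_deltas({"none": [12.0, 12.0, 12.0]})
        s = rs.summarize_by_grade(cohort)["none"]
        assert s.mean_pct_increase == pytest.approx(12.0)
        assert s.ci95[0] == pytest.approx(s.ci95[1])
        assert s.quartiles == pytest.approx((12.0, 12.0, 12.0))

    def test_two_record_t_interval_closed_form(self):
        cohort = _cohort_from_deltas({"none": [0.0, 10.0]})
        s = rs.summarize_by_grade(cohort)["none"]
        # mean 5, s = sqrt(50), sem = 5, t_{0.975, 1} = 12.706204736174698
        half = 12.706204736174698 * 5.0
        assert s.mean_pct_increase == pytest.approx(5.0)
        assert s.ci95 == pytest.approx((5.0 - half, 5.0 + half), rel=1e-10)

    def test_quartiles_linear_interpolation(self):
        cohort = _cohort_from_deltas({"none": [0.0, 10.0, 20.0, 30.0]})
        s = rs.summarize_by_grade(cohort)["none"]
        assert s.quartiles == pytest.approx((7.5, 15.0, 22.5))

    def test_missing_week5_excluded_and_counted(self):
        cohort = _cohort_from_deltas({"none": [5.0, None, 15.0, None]})
        s = rs.summarize_by_grade(cohort)["none"]
        assert s.n == 2 and s.n_missing == 2
        assert s.mean_pct_increase == pytest.approx(10.0)

    def test_sparse_grade_marked_unavailable(self):
        cohort = _cohort_from_deltas({"none": [5.0, 6.0], "proliferative": [9.0]})
        out = rs.summarize_by_grade(cohort)
        assert out["none"].available
        assert not out["proliferative"].available
        assert math.isnan(out["proliferative"].mean_pct_increase)
        assert not out["non_proliferative"].available

    def test_ci_contains_mean_and_quartiles_ordered(self, table1_cohort):
        for s in rs.summarize_by_grade(table1_cohort).values():
            if not s.available:
                continue
            assert s.ci95[0] <= s.mean_pct_increase <= s.ci95[1]
            q1, med, q3 = s.quartiles
            assert q1 <= med <= q3


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        res = rs.compare_groups([1, 2, 3], [1, 2, 3], mode="mann_whitney_u")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_small_sample_example(self):
        res = rs.compare_groups([1, 2, 3], [4, 5, 6], mode="mann_whitney_u")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.1, abs=1e-12)  # 2/20 assignments

    def test_large_shift_detected_by_both_tests(self, rng):
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(1.0, 1.0, 200)
        for mode in ("welch_t", "student_t", "mann_whitney_u"):
            assert rs.compare_groups(a, b, mode=mode).p_value < 1e-3

    def test_degenerate_pooled_values_undefined(self):
        res = rs.compare_groups([3.0, 3.0], [3.0, 3.0])
        assert not res.defined and math.isnan(res.p_value)

    def test_auto_gate_prefers_t_for_normal_data(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.2, 1, 100)
        assert rs.compare_groups(a, b, mode="auto").test_name == "welch_t"

    def test_auto_gate_prefers_mwu_for_skewed_data(self, rng):
        a = rng.lognormal(0, 1.5, 100)
        b = rng.lognormal(0.2, 1.5, 100)
        assert rs.compare_groups(a, b, mode="auto").test_name == "mann_whitney_u"

    @staticmethod
    def _mwu_oracle(a, b):
        """Independent brute force: enumerate every assignment of the pooled
        values into groups of the observed sizes."""
        pooled = np.r_[a, b]
        ranks = stats.rankdata(pooled)
        n1 = len(a)
        u_of = lambda ix: ranks[list(ix)].sum() - n1 * (n1 + 1) / 2
        u_obs = u_of(range(n1))
        us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
        le = sum(u <= u_obs + 1e-9 for u in us) / len(us)
        ge = sum(u >= u_obs - 1e-9 for u in us) / len(us)
        return u_obs, min(1.0, 2.0 * min(le, ge))

    @pytest.mark.parametrize("tied", [False, True])
    def test_exact_path_matches_brute_force(self, rng, tied):
        for _ in range(5):
            if tied:
                a = rng.integers(0, 4, 6).astype(float)
                b = rng.integers(0, 4, 5).astype(float)
                if np.ptp(np.r_[a, b]) == 0:
                    a[0] += 1.0
            else:
                a = rng.normal(size=6)
                b = rng.normal(size=5)
            res = rs.compare_groups(a, b, mode="mann_whitney_u")
            u, p = self._mwu_oracle(a, b)
            assert min(res.statistic, 30 - res.statistic) == pytest.approx(
                min(u, 30 - u)
            )  # n1*n2 - U: either group may anchor the statistic
            assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            rs.compare_groups([1, 2], [3, 4], mode="z_test")
        with pytest.raises(ValueError):
            rs.compare_groups([1], [2, 3], mode="welch_t")


class TestChiSquareAndAnova:
    def test_independent_table_gives_zero_statistic(self):
        res = rs.chi_square_2xk([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1.0

    def test_prospective_rop_by_tier_association(self):
        # ROP x risk-tier table from the prospective validation counts
        res = rs.chi_square_2xk([[3, 29], [0, 121]])
        assert res.p_value <= 0.05

    def test_pearson_statistic_and_p_from_reference_distribution(self):
        table = np.array([[12.0, 5.0], [8.0, 15.0]])
        # independent hand computation of the Pearson statistic
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum * colsum / table.sum()
        stat = float(((table - expected) ** 2 / expected).sum())
        res = rs.chi_square_2xk(table)
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(stat, 1)), abs=1e-8)

    def test_yates_correction_available(self):
        plain = rs.chi_square_2xk([[3, 29], [0, 121]])
        yates = rs.chi_square_2xk([[3, 29], [0, 121]], yates=True)
        assert yates.statistic < plain.statistic

    def test_chi_square_input_validation(self):
        with pytest.raises(ValueError):
            rs.chi_square_2xk([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            rs.chi_square_2xk([[0, 0], [1, 2]])

    def test_identical_groups_give_f_zero(self):
        res = rs.anova_oneway([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_anova_two_groups_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        f_res = rs.anova_oneway(a, b)
        t_res = rs.compare_groups(a, b, mode="student_t")
        assert f_res.statistic == pytest.approx(t_res.statistic**2, abs=1e-10)
        assert f_res.p_value == pytest.approx(t_res.p_value, abs=1e-10)

    def test_anova_f_and_p_from_reference_distribution(self, rng):
        groups = [rng.normal(m, 1, 20) for m in (0.0, 0.3, 0.6)]
        res = rs.anova_oneway(*groups)
        k, n = 3, 60
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(
            float(stats.f.sf(f, k - 1, n - k)), abs=1e-8
        )

    def test_anova_input_validation(self):
        with pytest.raises(ValueError):
            rs.anova_oneway([1.0, 2.0])
        with pytest.raises(ValueError):
            rs.anova_oneway([1.0, 2.0], [3.0])

    def test_grade_comparison_on_simulated_cohort(self, table1_cohort):
        """Three-grade ANOVA on the percentage increases runs end to end."""
        f = table1_cohort.frame
        delta = 100.0 * (f["igf1_w5"] - f["igf1_w3"]) / f["igf1_w3"]
        groups = [delta[f["rop_grade"] == g].to_numpy() for g in rs.ROP_GRADES]
        res = rs.anova_oneway(*groups)
        assert res.defined and 0.0 <= res.p_value <= 1.0
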