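"""t-based CIs, two-group t-tests, stage-stratified tests, and the
chi-squared demographics association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from exomirdx import (
    CohortConfig,
    InvalidParameterError,
    MirnaGroupSpec,
    UndefinedMetricError,
    adjust_pvalues,
    age_ttest,
    chi_squared_demographics,
    ci99_mean,
    differential_tests,
    generate_cohort,
    group_summaries,
    preprocess_cohort,
    significance_stars,
    stage_stratified_tests,
    two_group_ttest,
)

# Cauchy quantile: the 99.5th t percentile at 1 df has the closed form
# tan(pi * 0.495).
T995_DF1 = np.tan(np.pi * 0.495)


class TestCiMean:
    def test_constant_vector_zero_width(self):
        assert ci99_mean([4.2, 4.2, 4.2]) == (pytest.approx(4.2), pytest.approx(4.2))

    def test_n2_closed_form(self):
        # values {0, 2}: mean 1, sd sqrt(2), half-width t * sqrt(2)/sqrt(2)
        lo, hi = ci99_mean([0.0, 2.0])
        assert lo == pytest.approx(1.0 - T995_DF1)
        assert hi == pytest.approx(1.0 + T995_DF1)

    def test_requires_two_values(self):
        with pytest.raises(InvalidParameterError):
            ci99_mean([1.0])

    def test_exact_moments_reproduce_printed_interval(self, moments_vector):
        from exomirdx import derive_group_params_from_ci

        mean, sd = derive_group_params_from_ci(7.99, 9.60, 19)
        lo, hi = ci99_mean(moments_vector(mean, sd, 19))
        assert (round(lo, 2), round(hi, 2)) == (7.99, 9.60)


class TestTTest:
    def test_identical_groups_degenerate(self):
        r = two_group_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_pooled_formula_oracle(self):
        """Textbook pooled-variance computation, written out explicitly."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t_manual = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        from scipy import stats

        p_manual = 2 * stats.t.sf(abs(t_manual), df=len(x) + len(y) - 2)
        r = two_group_ttest(x, y, variant="student")
        assert r.statistic == pytest.approx(t_manual)
        assert r.p_value == pytest.approx(p_manual)

    def test_welch_differs_under_unequal_variance(self):
        x = [1.0, 1.1, 0.9, 1.05]
        y = [2.0, 6.0, -1.0, 4.0, 0.0]
        rs = two_group_ttest(x, y, "student")
        rw = two_group_ttest(x, y, "welch")
        assert rs.df != rw.df

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=8),
        st.lists(st.floats(-5, 5), min_size=3, max_size=8),
    )
    def test_symmetry(self, x, y):
        a = two_group_ttest(x, y)
        b = two_group_ttest(y, x)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-9)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(InvalidParameterError):
            two_group_ttest([1.0], [1.0, 2.0])


class TestStars:
    @pytest.mark.parametrize(
        "p,thr,stars",
        [
            (0.2, None, "ns"),
            (0.04, 0.05, "*"),
            (0.009, 0.01, "**"),
            (0.0005, 0.001, "***"),
            (0.05, None, "ns"),  # boundary: strict '<'
        ],
    )
    def test_ladder(self, p, thr, stars):
        assert significance_stars(p) == (thr, stars)


class TestCohortLevel:
    def test_group_summaries_structure(self, delta_matrix, metadata):
        s = group_summaries(delta_matrix, metadata)
        assert set(s["group"]) == {"control", "pdac", "early", "mid", "late"}
        ctrl = s[s["group"] == "control"]
        assert (ctrl["n"] == 19).all()
        assert (ctrl["ci_low"] <= ctrl["mean"]).all()
        assert (ctrl["mean"] <= ctrl["ci_high"]).all()

    def test_differential_tests_cover_retained(self, delta_matrix, metadata):
        t = differential_tests(delta_matrix, metadata)
        assert set(t["mirna_id"]) == set(delta_matrix.retained_mirnas)
        assert ((t["p_value"] >= 0) & (t["p_value"] <= 1)).all()

    def test_stage_tests_buckets(self, delta_matrix, metadata):
        t = stage_stratified_tests(delta_matrix, metadata)
        assert set(t["comparison"]) == {
            "control_vs_early", "control_vs_mid", "control_vs_late"
        }

    def test_empty_bucket_skipped(self, delta_matrix, metadata, caplog):
        meta = metadata.copy()
        meta.loc[meta["stage_bucket"] == "mid", "stage_bucket"] = "late"
        with caplog.at_level("WARNING"):
            t = stage_stratified_tests(delta_matrix, meta)
        assert "control_vs_mid" not in set(t["comparison"])

    def test_early_stage_shift_detected_in_most_replicates(self):
        """Power check: with the miR-425-5p group shift applied to all
        stages, early-vs-control is significant in most cohorts."""
        from exomirdx import derive_group_params_from_ci

        c_mean, c_sd = derive_group_params_from_ci(7.67, 9.16, 19)
        p_mean, p_sd = derive_group_params_from_ci(9.59, 11.51, 15)
        spec = MirnaGroupSpec("miR-425-5p", c_mean, c_sd, p_mean, p_sd, 1.0)
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            raw, meta = generate_cohort(
                CohortConfig(mirna_specs=[spec], seed=seed)
            )
            t = stage_stratified_tests(preprocess_cohort(raw), meta)
            row = t[(t["comparison"] == "control_vs_early")].iloc[0]
            hits += row["p_value"] < 0.05
        assert hits > n_rep / 2


class TestChiSquared:
    def _meta(self, ctrl_counts, pdac_counts, cats=("M", "F")):
        rows = []
        for grp, counts in (("control", ctrl_counts), ("pdac", pdac_counts)):
            for cat, k in zip(cats, counts):
                rows += [{"group": grp, "sex": cat}] * k
        return pd.DataFrame(rows)

    def test_study_sex_table_matches_manual_pearson(self):
        """13M/6F controls vs 13M/2F PDAC: statistic from the explicit
        expected-count formula; association not significant."""
        meta = self._meta([13, 6], [13, 2])
        obs = np.array([[13.0, 6.0], [13.0, 2.0]])
        exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
        chi2_manual = ((obs - exp) ** 2 / exp).sum()
        r = chi_squared_demographics(meta, "sex")
        assert r.statistic == pytest.approx(chi2_manual)
        assert r.p_value > 0.05

    def test_identical_distributions_zero_statistic(self):
        meta = self._meta([10, 10], [5, 5])
        r = chi_squared_demographics(meta, "sex")
        assert r.statistic == pytest.approx(0.0)

    def test_empty_category_dropped(self, caplog):
        meta = self._meta([10, 0, 5], [5, 0, 5], cats=("A", "B", "C"))
        with caplog.at_level("WARNING"):
            r = chi_squared_demographics(meta, "sex")
        assert r.df == 1.0  # 2x2 after dropping the empty category

    def test_single_category_undefined(self):
        meta = self._meta([10], [5], cats=("M",))
        with pytest.raises(UndefinedMetricError):
            chi_squared_demographics(meta, "sex")

    def test_age_is_binned(self, metadata):
        r = chi_squared_demographics(metadata, "age")
        assert r.test == "chi2" and 0 <= r.p_value <= 1

    def test_age_ttest_runs(self, metadata):
        r = age_ttest(metadata)
        assert r.comparison == "age_control_vs_pdac"


def test_bh_adjustment_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = adjust_pvalues(p)
    assert (adj >= np.asarray(p) - 1e-12).all()
    assert (adj <= 1.0).all()
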