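"""Paired tests, trajectory patterns, mixed model and contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from anoscore.longitudinal import (classify_trajectory, fit_lme,
                                   paired_t_test, predict_contrasts,
                                   run_analysis)
from anoscore.phantoms import CohortGenSpec, generate_cohort


class TestPairedT:
    def test_textbook_example(self):
        # a=(1,2,4), b=(2,2,5): differences (-1,0,-1), t=-2, df=2
        res = paired_t_test([1, 2, 4], [2, 2, 5])
        assert res.mean_diff == pytest.approx(-2.0 / 3.0)
        assert res.t == pytest.approx(-2.0, abs=1e-12)
        assert res.df == 2
        expected_p = 2.0 * stats.t.sf(2.0, 2)
        assert res.p == pytest.approx(expected_p, abs=1e-12)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_rejected(self):
        # zero variance of differences even though values differ
        with pytest.raises(ValueError, match="variance"):
            paired_t_test([1, 2, 3], [2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            paired_t_test([1.0], [2.0])

    def test_nan_pairs_dropped(self):
        res = paired_t_test([1, 2, 4, np.nan], [2, 2, 5, 1])
        assert res.n_pairs == 3

    def test_matches_scipy_on_random_samples(self):
        # independent-oracle equivalence over 100 random small samples
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n)
            b = a + rng.normal(0.5, 1.0, size=n)
            ours = paired_t_test(a, b)
            ref = stats.ttest_rel(a, b)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestTrajectory:
    @pytest.mark.parametrize("triple,expected", [
        ((5.0, 3.0, 1.0), "decreasing"),
        ((1.0, 3.0, 5.0), "increasing"),
        ((1.0, 3.0, 1.0), "inc_dec"),
        ((3.0, 1.0, 3.0), "dec_inc"),
        ((1.0, 1.05, 1.0), "flat"),
    ])
    def test_patterns(self, triple, expected):
        assert classify_trajectory(*triple, tol=0.1) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_trajectory(1.0, np.nan, 2.0)

    @given(z=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
           tol=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_and_exclusive(self, z, tol):
        out = classify_trajectory(*z, tol=tol)
        assert out in {"decreasing", "increasing", "inc_dec", "dec_inc", "flat"}


class TestLme:
    truth = {"days": 0.004, "expander": 2.223, "age": 0.073,
             "intercept": -2.39}

    def noise_free_cohort(self):
        return generate_cohort(CohortGenSpec(
            n_patients=40, fixed_effects=self.truth,
            random_intercept_sd=0.0, residual_sd=0.0, seed=1))

    def test_noise_free_interpolation(self):
        fit = fit_lme(self.noise_free_cohort(), response="as_true")
        for term, value in self.truth.items():
            assert fit.coefficients[term].estimate == pytest.approx(
                value, abs=1e-6)
        for term in ("hypo", "scl", "imn", "boost", "imrt",
                     "complication", "bmi_gt23", "nsm_ssm"):
            assert fit.coefficients[term].estimate == pytest.approx(
                0.0, abs=1e-6)

    def test_single_patient_rejected(self):
        cohort = generate_cohort(CohortGenSpec(n_patients=1, seed=0))
        with pytest.raises(ValueError, match="patients"):
            fit_lme(cohort, response="as_true")

    def test_rank_deficiency_named(self):
        cohort = generate_cohort(CohortGenSpec(n_patients=30, seed=2))
        cohort["plan"] = "3d"             # imrt column becomes all-zero
        with pytest.raises(ValueError, match="imrt"):
            fit_lme(cohort, response="as_true")

    def test_ci_brackets_estimate_and_wald_p(self):
        cohort = generate_cohort(CohortGenSpec(n_patients=80, seed=3))
        fit = fit_lme(cohort, response="as_true")
        assert fit.converged
        for ce in fit.coefficients.values():
            assert ce.ci_low <= ce.estimate <= ce.ci_high
            z = abs(ce.estimate / ce.std_error)
            assert ce.p_value == pytest.approx(2 * stats.norm.sf(z), abs=1e-12)

    def test_variance_components_recovered_roughly(self):
        cohort = generate_cohort(CohortGenSpec(n_patients=400, seed=5))
        fit = fit_lme(cohort, response="as_true")
        assert fit.random_intercept_sd == pytest.approx(1.5, rel=0.15)
        assert fit.residual_sd == pytest.approx(1.0, rel=0.15)


class TestContrasts:
    def fitted(self):
        cohort = generate_cohort(CohortGenSpec(
            n_patients=120, fixed_effects={"expander": 2.0,
                                           "expander_x_days": 0.001},
            residual_sd=0.5, seed=8))
        return fit_lme(cohort, response="as_true")

    def test_day_zero_equals_main_effect(self):
        fit = self.fitted()
        c0 = predict_contrasts(fit, days_grid=[0.0])[0]
        assert c0.estimate == fit.coefficients["expander"].estimate
        assert c0.ci_low <= c0.estimate <= c0.ci_high

    def test_linear_arithmetic(self):
        # synthetic coefficients: 2.0 + 500 * 0.001 = 2.5
        fit = self.fitted()
        fit.coefficients["expander"] = fit.coefficients["expander"].__class__(
            2.0, 0.1, 1.8, 2.2, 0.01)
        fit.coefficients["expander_x_days"] = \
            fit.coefficients["expander_x_days"].__class__(
                0.001, 0.0001, 0.0008, 0.0012, 0.01)
        c = predict_contrasts(fit, days_grid=[500.0])[0]
        assert c.estimate == pytest.approx(2.5, abs=1e-12)

    def test_zero_interaction_gives_flat_contrast(self):
        fit = self.fitted()
        fit.coefficients["expander_x_days"] = \
            fit.coefficients["expander_x_days"].__class__(0.0, 0.1, -0.2, 0.2, 1.0)
        ests = [c.estimate for c in
                predict_contrasts(fit, days_grid=[0, 180, 720])]
        assert ests[0] == ests[1] == ests[2]

    def test_missing_term_rejected(self):
        fit = self.fitted()
        with pytest.raises(ValueError, match="not in the fitted model"):
            predict_contrasts(fit, main="chemo")


class TestRunAnalysis:
    def test_degenerate_cohort_reported_not_crashed(self):
        cohort = generate_cohort(CohortGenSpec(
            n_patients=10, fixed_effects={"intercept": 1.0},
            random_intercept_sd=0.0, residual_sd=0.0, seed=0))
        report = run_analysis(cohort, response="as_true")
        overall = report.pairwise_tests.query("stratum == 'overall'")
        assert overall["note"].str.contains("degenerate").all()

    def test_expander_stratum_scores_higher(self):
        cohort = generate_cohort(CohortGenSpec(
            n_patients=150, fixed_effects={"expander": 5.0},
            random_intercept_sd=0.2, residual_sd=0.2, seed=1))
        means = cohort.groupby(["visit", "recon_type"])["as_true"].mean()
        for visit in ("pre_rt", "post_1y", "post_2y"):
            assert means[visit, "expander"] > means[visit, "autologous"]
        report = run_analysis(cohort, response="as_true")
        assert set(report.contrasts["contrast"]) == {"expander", "hypo"}

    def test_rerun_is_byte_identical(self, tmp_path):
        cohort = generate_cohort(CohortGenSpec(n_patients=40, seed=6))
        for d in ("a", "b"):
            run_analysis(cohort, response="as_true").write(tmp_path / d)
        for name in ("pairwise_tests.csv", "trajectories.csv",
                     "contrasts.csv", "lme_fit.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
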