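"""Statistics layer: test-selection tree, moderation models, simple slopes,
effect sizes and trajectory smoothing."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from scnkit import (
    fit_moderation_model,
    fit_trajectory,
    model_effect_sizes,
    select_and_compare,
    simple_slopes,
)
from scnkit.longstats import cohens_f2

TIMEPOINTS = [0.0, 1.0, 2.0, 3.0, 6.0, 12.0]


def _cohort(
    rng,
    n_subj=40,
    beta_metric=-6.137,
    beta_group=2.0,
    beta_int=9.087,
    beta_time=0.5,
    subject_sd=0.5,
    noise_sd=1.0,
    metric_sd=0.5,
):
    """Two-group longitudinal cohort with a planted moderation structure."""
    n_t = len(TIMEPOINTS)
    subj = np.repeat([f"S{i:03d}" for i in range(n_subj)], n_t)
    grp = np.where(
        np.repeat(np.arange(n_subj) < n_subj // 2, n_t), "sci_only", "treatment"
    )
    tp = np.tile(TIMEPOINTS, n_subj)
    metric = rng.normal(0.5, metric_sd, subj.size)
    g = (grp == "treatment").astype(float)
    u = np.repeat(rng.normal(0.0, subject_sd, n_subj), n_t)
    y = (
        30.0 + beta_metric * metric + beta_group * g + beta_int * metric * g
        + beta_time * tp + u + rng.normal(0.0, noise_sd, subj.size)
    )
    return y, metric, grp, tp, subj


class TestDecisionTree:
    def test_gaussian_equal_variance_selects_student_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.3, 1, 50)
        res = select_and_compare(a, b)
        assert res.test_name == "independent_t"
        assert any("levene" in t for t in res.decision_trace)
        assert res.ci is not None

    def test_unequal_variances_select_welch(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 80)
        b = rng.normal(0, 6, 80)
        res = select_and_compare(a, b)
        assert res.test_name == "welch_t"

    def test_skewed_sample_selects_mann_whitney(self, rng):
        a = rng.exponential(1.0, 50)  # heavily skewed
        b = rng.normal(1.0, 1.0, 50)
        res = select_and_compare(a, b)
        assert res.test_name == "mann_whitney_u"
        assert res.effect_size_name == "rank_biserial"

    def test_paired_normal_differences_select_paired_t(self, rng):
        base = rng.normal(0, 1, 30)
        follow = base + rng.normal(0.5, 0.5, 30)
        res = select_and_compare(follow, base, paired=True)
        assert res.test_name == "paired_t"

    def test_paired_skewed_differences_select_wilcoxon(self, rng):
        base = rng.normal(0, 1, 40)
        follow = base + rng.exponential(1.0, 40)
        res = select_and_compare(follow, base, paired=True)
        assert res.test_name == "wilcoxon_signed_rank"

    def test_constant_paired_differences_rejected(self):
        a = np.arange(10.0)
        with pytest.raises(ValueError, match="constant"):
            select_and_compare(a, a, paired=True)

    def test_paired_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal-length"):
            select_and_compare(rng.normal(size=5), rng.normal(size=6), paired=True)

    def test_identical_inputs_identical_decision(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        r1 = select_and_compare(a, b)
        r2 = select_and_compare(a, b)
        assert r1 == r2


class TestModerationModel:
    def test_matches_ols_when_no_clustering(self, rng):
        """With zero subject variance the mixed model reduces to OLS."""
        y, m, g, tp, s = _cohort(rng, n_subj=100, subject_sd=0.0)
        fit = fit_moderation_model(y, m, g, tp, s, with_effect_sizes=False)
        gd = (g == "treatment").astype(float)
        x = np.column_stack(
            [np.ones_like(y), m, gd, m * gd]
            + [(tp == t).astype(float) for t in TIMEPOINTS[1:]]
        )
        ols = sm.OLS(y, x).fit()
        np.testing.assert_allclose(
            fit.coefficients["beta"].to_numpy(), ols.params, rtol=1e-3
        )

    def test_noiseless_limit_recovers_exact_coefficients(self, rng):
        y, m, g, tp, s = _cohort(rng, n_subj=20, subject_sd=0.0, noise_sd=1e-6)
        fit = fit_moderation_model(y, m, g, tp, s, with_effect_sizes=False)
        assert fit.beta("metric") == pytest.approx(-6.137, abs=1e-4)
        assert fit.beta("metric:group") == pytest.approx(9.087, abs=1e-4)
        assert fit.beta("timepoint[12]") == pytest.approx(6.0, abs=1e-4)

    def test_planted_interaction_recovered_at_low_noise(self, rng):
        y, m, g, tp, s = _cohort(rng, noise_sd=0.3)
        fit = fit_moderation_model(y, m, g, tp, s)
        assert fit.beta("metric:group") == pytest.approx(9.087, abs=0.5)
        assert fit.df_method == "satterthwaite"
        ci = fit.coefficients.loc["metric:group", ["ci_low", "ci_high"]]
        assert ci[0] < 9.087 < ci[1]

    def test_single_group_rejected(self, rng):
        y, m, g, tp, s = _cohort(rng, n_subj=10)
        g = np.full_like(g, "sci_only")
        with pytest.raises(ValueError, match="two groups"):
            fit_moderation_model(y, m, g, tp, s)

    def test_r2_ordering_and_bounds(self, rng):
        y, m, g, tp, s = _cohort(rng)
        fit = fit_moderation_model(y, m, g, tp, s)
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0
        assert fit.f2_interaction >= 0.0


class TestSimpleSlopes:
    def test_reference_coding_identity(self, rng):
        """slope(treatment) - slope(reference) must equal the interaction
        estimate to 1e-10 on every fitted model."""
        for seed in range(5):
            y, m, g, tp, s = _cohort(np.random.default_rng(seed), n_subj=16)
            fit = fit_moderation_model(y, m, g, tp, s, with_effect_sizes=False)
            slopes, diff = simple_slopes(fit)
            gap = slopes.loc["treatment", "slope"] - slopes.loc["sci_only", "slope"]
            assert gap == pytest.approx(diff["estimate"], abs=1e-10)

    def test_printed_triple_scenario(self, rng):
        """Planted truth (-6.137, +9.087): the fitted per-group slopes land on
        -6.137 and 2.950, and their difference is the interaction."""
        y, m, g, tp, s = _cohort(rng, n_subj=60, noise_sd=0.05, subject_sd=0.1)
        fit = fit_moderation_model(y, m, g, tp, s, with_effect_sizes=False)
        slopes, diff = simple_slopes(fit)
        assert slopes.loc["sci_only", "slope"] == pytest.approx(-6.137, abs=0.05)
        assert slopes.loc["treatment", "slope"] == pytest.approx(2.950, abs=0.05)
        assert -6.137 + 9.087 == pytest.approx(2.950, abs=1e-12)

    def test_zero_interaction_gives_equal_slopes(self, rng):
        y, m, g, tp, s = _cohort(rng, beta_int=0.0, noise_sd=1e-6, subject_sd=0.0)
        fit = fit_moderation_model(y, m, g, tp, s, with_effect_sizes=False)
        slopes, _ = simple_slopes(fit)
        assert slopes.loc["treatment", "slope"] == pytest.approx(
            slopes.loc["sci_only", "slope"], abs=1e-3
        )

    def test_ci_contains_point_estimate(self, rng):
        y, m, g, tp, s = _cohort(rng)
        fit = fit_moderation_model(y, m, g, tp, s, with_effect_sizes=False)
        slopes, _ = simple_slopes(fit)
        assert np.all(slopes["ci_low"] <= slopes["slope"])
        assert np.all(slopes["slope"] <= slopes["ci_high"])

    def test_missing_interaction_rejected(self, rng):
        y, m, g, tp, s = _cohort(rng, n_subj=10)
        fit = fit_moderation_model(
            y, m, g, tp, s, include_interaction=False, with_effect_sizes=False
        )
        with pytest.raises(ValueError, match="interaction"):
            simple_slopes(fit)


class TestAgainstReferenceImplementation:
    def test_matches_lmerTest_satterthwaite(self, tmp_path, rng):
        """Estimates, SEs and Satterthwaite df agree with lme4/lmerTest on
        the same data (independent reference implementation via Rscript)."""
        import subprocess

        y, m, g, tp, s = _cohort(rng, n_subj=12)
        import pandas as pd

        csv = tmp_path / "lmm.csv"
        pd.DataFrame({"y": y, "metric": m, "group": g, "tp": tp, "subj": s}).to_csv(
            csv, index=False
        )
        fit = fit_moderation_model(y, m, g, tp, s, with_effect_sizes=False)
        r_code = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv('{csv}')
        d$group <- relevel(factor(d$group), ref='sci_only')
        d$tp <- factor(d$tp)
        mod <- lmer(y ~ metric*group + tp + (1|subj), data=d, REML=TRUE)
        co <- coef(summary(mod))
        r <- co['metric:grouptreatment', ]
        cat(sprintf('%.6f %.6f %.4f', r[1], r[2], r[3]))
        """
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
        )
        beta_r, se_r, df_r = map(float, out.stdout.split())
        row = fit.coefficients.loc["metric:group"]
        assert row["beta"] == pytest.approx(beta_r, abs=1e-4)
        assert row["se"] == pytest.approx(se_r, abs=1e-4)
        assert row["df"] == pytest.approx(df_r, rel=0.01)


class TestEffectSizes:
    def test_f2_from_r2_pair(self):
        assert cohens_f2(0.5, 0.4) == pytest.approx(0.2, abs=1e-15)

    def test_f2_undefined_at_perfect_fit(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_f2(1.0, 0.5)

    def test_null_interaction_has_small_median_f2(self):
        f2s = []
        for seed in range(60):
            rng = np.random.default_rng(3000 + seed)
            y, m, g, tp, s = _cohort(rng, n_subj=40, beta_int=0.0)
            fit = fit_moderation_model(y, m, g, tp, s)
            f2s.append(fit.f2_interaction)
        assert float(np.median(f2s)) < 0.02

    def test_marginal_equals_conditional_without_random_variance(self, rng):
        y, m, g, tp, s = _cohort(rng, n_subj=60, subject_sd=0.0)
        fit = fit_moderation_model(y, m, g, tp, s)
        assert fit.r2_conditional == pytest.approx(fit.r2_marginal, abs=0.02)


def _trajectory_data(rng, n_subj=8, slope=0.3, curve=None, subject_sd=0.3, noise_sd=0.2):
    months = np.tile(TIMEPOINTS, n_subj)
    subj = np.repeat([f"S{i}" for i in range(n_subj)], len(TIMEPOINTS))
    f = slope * months if curve is None else curve(months)
    y = 1.0 + f + np.repeat(rng.normal(0, subject_sd, n_subj), len(TIMEPOINTS))
    y = y + rng.normal(0, noise_sd, months.size)
    return y, months, subj


class TestTrajectory:
    def test_linear_truth_typically_gives_unit_edf(self):
        """Linear-in-time data: the smoothing penalty should shrink the fit
        to a line (median edf near 1) with the slope inside 2 SE of truth."""
        edfs, hits = [], []
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            y, months, subj = _trajectory_data(rng)
            fit = fit_trajectory(y, months, subj)
            edfs.append(fit.edf)
            hits.append(abs(fit.slope - 0.3) <= 2 * fit.slope_se)
        assert float(np.median(edfs)) <= 1.3
        assert np.mean(hits) >= 0.7

    def test_curved_truth_raises_edf_and_rejects_flatness(self, rng):
        y, months, subj = _trajectory_data(
            rng, curve=lambda m: 2.0 * np.sin(np.pi * m / 12.0), noise_sd=0.1
        )
        fit = fit_trajectory(y, months, subj)
        assert fit.edf > 1.5
        assert fit.p_smooth < 0.01

    def test_deterministic_selection_and_curve(self, rng):
        y, months, subj = _trajectory_data(rng)
        f1 = fit_trajectory(y, months, subj)
        f2 = fit_trajectory(y, months, subj)
        assert f1.k_selected == f2.k_selected
        pd.testing.assert_frame_equal(f1.fitted_curve, f2.fitted_curve)

    def test_edf_within_bounds(self, rng):
        y, months, subj = _trajectory_data(rng, curve=lambda m: 0.05 * (m - 6) ** 2)
        fit = fit_trajectory(y, months, subj)
        assert 1.0 <= fit.edf + 1e-9
        assert fit.edf <= fit.k_selected

    def test_too_few_distinct_times_rejected(self, rng):
        y = rng.normal(size=9)
        months = np.tile([0.0, 1.0, 2.0], 3)
        subj = np.repeat(["a", "b", "c"], 3)
        with pytest.raises(ValueError, match="distinct time"):
            fit_trajectory(y, months, subj)

    def test_out_of_range_k_rejected(self, rng):
        y, months, subj = _trajectory_data(rng)
        with pytest.raises(ValueError, match="k_candidates"):
            fit_trajectory(y, months, subj, k_candidates=[2, 3])
        with pytest.raises(ValueError, match="k_candidates"):
            fit_trajectory(y, months, subj, k_candidates=[10])

    def test_curve_defined_on_observed_range_only(self, rng):
        y, months, subj = _trajectory_data(rng)
        fit = fit_trajectory(y, months, subj)
        assert fit.fitted_curve["month"].min() == pytest.approx(0.0)
        assert fit.fitted_curve["month"].max() == pytest.approx(12.0)
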