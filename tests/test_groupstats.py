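import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from hemigait import groupstats as gs
from hemigait.groupstats import ModelError

from conftest import simulate_lmm_table


class TestCenterSpeed:
    def test_grand_mean_centering(self):
        np.testing.assert_allclose(gs.center_speed([0.5, 1.0, 1.5]), [-0.5, 0.0, 0.5])

    def test_idempotence(self):
        centered = gs.center_speed([0.4, 0.8, 1.2])
        np.testing.assert_allclose(gs.center_speed(centered), centered, atol=1e-12)

    def test_single_speed_rejected(self):
        with pytest.raises(ModelError):
            gs.center_speed([0.8, 0.8, 0.8])


class TestClassicalFit:
    def test_zero_noise_exact_interpolation(self):
        table = simulate_lmm_table(0, n_participants=12, tau=0.0, sigma=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = gs.fit_metric_model(table, "sla", estimator="classical")
        sbar = table.speed_mps.mean()
        truth = np.array([0.1 - 0.08 * sbar, 0.08 - 0.05 * sbar, -0.08, -0.05])
        np.testing.assert_allclose(fit.coef, truth, atol=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        table = simulate_lmm_table(3, n_participants=30)
        fit = gs.fit_metric_model(table, "sla", estimator="classical")
        d = table.copy()
        d["g"] = (d.group == "stroke").astype(float)
        d["sc"] = d.speed_mps - d.speed_mps.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm("sla ~ g*sc", d, groups=d["participant_id"]).fit(reml=True)
        np.testing.assert_allclose(fit.coef, ref.params.values[:4], atol=1e-4)
        # statsmodels' default optimizer converges less tightly than the
        # profiled 1-D search; agree to ~1%
        np.testing.assert_allclose(fit.se, ref.bse.values[:4], rtol=1e-2)
        assert fit.sigma2 == pytest.approx(float(ref.scale), rel=2e-2)
        assert fit.tau2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=5e-2)

    def test_satterthwaite_matches_r_lmertest(self, tmp_path):
        """Coefficients, SEs, Satterthwaite df and p-values against lmerTest."""
        table = simulate_lmm_table(7, n_participants=24)
        fit = gs.fit_metric_model(table, "sla", estimator="classical")
        d = table.copy()
        d["g"] = (d.group == "stroke").astype(int)
        csv = tmp_path / "lmm.csv"
        d.to_csv(csv, index=False)
        out = tmp_path / "coefs.csv"
        r_code = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        d$sc <- d$speed_mps - mean(d$speed_mps)
        m <- lmer(sla ~ g*sc + (1|participant_id), data=d, REML=TRUE)
        write.csv(summary(m)$coefficients, "{out}")
        """
        subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
        ref = pd.read_csv(out, index_col=0)
        np.testing.assert_allclose(fit.coef, ref["Estimate"].values, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref["Std. Error"].values, atol=1e-6)
        np.testing.assert_allclose(fit.df, ref["df"].values, rtol=1e-3)
        np.testing.assert_allclose(fit.p_values, ref["Pr(>|t|)"].values, rtol=1e-3, atol=1e-8)

    def test_centering_invariance_of_slope_terms(self):
        """Slope and interaction estimates are invariant to the centering
        shift; the group contrast at the mean speed equals the centered
        group coefficient."""
        table = simulate_lmm_table(11, n_participants=24)
        fit = gs.fit_metric_model(table, "sla", estimator="classical")
        shifted = table.copy()
        shifted["speed_mps"] = shifted["speed_mps"] + 5.0  # same centered design
        fit2 = gs.fit_metric_model(shifted, "sla", estimator="classical")
        np.testing.assert_allclose(fit.coef, fit2.coef, atol=1e-8)

    def test_singular_random_effect_falls_back_with_warning(self):
        # noise centered within each participant: between-participant variance
        # below its expectation drives the REML variance ratio to the boundary
        table = simulate_lmm_table(13, n_participants=16, tau=0.0, sigma=0.05)
        table["sla"] = table.sla - table.groupby("participant_id").sla.transform("mean")
        with pytest.warns(UserWarning, match="boundary"):
            fit = gs.fit_metric_model(table, "sla", estimator="classical")
        assert fit.singular_random_effect
        assert np.all(fit.se > 0)

    def test_fewer_than_two_participants_per_group_rejected(self):
        table = simulate_lmm_table(1, n_participants=8)
        solo = table[table.participant_id.isin(["P000", "P004", "P005", "P006"])]
        with pytest.raises(ModelError, match="fewer than 2"):
            gs.fit_metric_model(solo, "sla")


class TestRobustFit:
    def test_infinite_tuning_constant_reproduces_classical(self):
        table = simulate_lmm_table(17, n_participants=24)
        classical = gs.fit_metric_model(table, "sla", estimator="classical")
        robust = gs.fit_metric_model(table, "sla", estimator="robust",
                                     tuning_constant=np.inf)
        assert np.max(np.abs(robust.coef - classical.coef)) < 1e-6

    def test_clean_gaussian_data_equivalence(self):
        """Without outliers the robust and classical coefficients agree to a
        fraction of a standard error (averaged across replicates)."""
        diffs = []
        for seed in range(5):
            table = simulate_lmm_table(seed, n_participants=30)
            c = gs.fit_metric_model(table, "sla", estimator="classical")
            r = gs.fit_metric_model(table, "sla", estimator="robust")
            diffs.append(np.max(np.abs(r.coef - c.coef) / c.se))
        assert np.mean(diffs) < 0.5

    def test_outlier_displaces_robust_less_than_classical(self):
        table = simulate_lmm_table(19, n_participants=30)
        c0 = gs.fit_metric_model(table, "sla", estimator="classical")
        r0 = gs.fit_metric_model(table, "sla", estimator="robust")
        spiked = table.copy()
        idx = spiked[spiked.group == "stroke"].speed_mps.idxmax()
        spiked.loc[idx, "sla"] += 10 * np.sqrt(c0.sigma2)
        c1 = gs.fit_metric_model(spiked, "sla", estimator="classical")
        r1 = gs.fit_metric_model(spiked, "sla", estimator="robust")
        dc, dr = c1.coef - c0.coef, r1.coef - r0.coef
        assert np.linalg.norm(dr) < np.linalg.norm(dc)


class TestFitAllMetrics:
    def test_group_coefficient_signs_match_generator_construction(self, small_cohort_tables):
        table, _ = small_cohort_tables
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = {f.metric: f for f in gs.fit_all_metrics(table, estimator="robust")}
        expected_sign = dict(sla=1, dlsta=1, slsta=1, hip_hike_deg=1,
                             circumduction_m=1, knee_flex_deg=-1, tla_deg=-1)
        for metric, sign in expected_sign.items():
            beta_group = fits[metric].coef[1]
            assert np.sign(beta_group) == sign, metric

    def test_missing_metric_rows_dropped_listwise(self, small_cohort_tables):
        table, _ = small_cohort_tables
        spoiled = table.copy()
        drop_ids = spoiled.participant_id.unique()[:2]
        spoiled.loc[spoiled.participant_id.isin(drop_ids), "hip_hike_deg"] = np.nan
        fit_hh = gs.fit_metric_model(spoiled, "hip_hike_deg", estimator="classical")
        fit_sla = gs.fit_metric_model(spoiled, "sla", estimator="classical")
        assert fit_hh.n_participants == fit_sla.n_participants - 2

    def test_sparse_metric_skipped_with_warning(self, small_cohort_tables):
        table, _ = small_cohort_tables
        sparse = table.copy()
        sparse.loc[sparse.index[5:], "hip_hike_deg"] = np.nan
        with pytest.warns(UserWarning, match="skipped"):
            fits = gs.fit_all_metrics(sparse, estimator="classical")
        assert "hip_hike_deg" not in {f.metric for f in fits}

    def test_results_table_schema(self, small_cohort_tables):
        table, _ = small_cohort_tables
        fits = [gs.fit_metric_model(table, "sla", estimator="classical")]
        out = gs.results_table(fits)
        assert list(out.columns) == ["metric", "term", "estimate", "se", "df", "p"]
        assert (out.p > 0).all() and (out.p <= 1).all()
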