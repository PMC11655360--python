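import numpy as np
import pandas as pd
import pytest

from bwasdesign import (
    ModelSpec,
    SimConfig,
    Term,
    fit_between_within,
    fit_study_model,
    remove_site_effects,
    simulate_longitudinal_study,
    wald_test,
)
from bwasdesign.cohort import CROSS_SECTIONAL, LONGITUDINAL, CohortTable
from bwasdesign.synthetic import SiteConfig, inject_site_effects


def _table_from_arrays(design=CROSS_SECTIONAL, **cols):
    n = len(next(iter(cols.values())))
    base = {
        "subject_id": [f"s{i}" for i in range(n)],
        "visit_index": 0,
        "age": 50.0,
        "sex": 0,
        "site_id": "site_0",
        "study_id": "study_0",
    }
    base.update(cols)
    return CohortTable(pd.DataFrame(base), design=design,
                       covariates=["x"] if "x" in cols else [], outcomes=["y"])


class TestFitStudyModel:
    def test_ols_recovers_slope_within_3_se(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        t = _table_from_arrays(x=x, y=y)
        fit = fit_study_model(t, ModelSpec("y", [Term("x")]))
        se = np.sqrt(fit.robust_cov.loc["x", "x"])
        assert abs(fit.beta_hat["x"] - 0.5) < 3 * se

    def test_constant_outcome_gives_null_wald(self, rng):
        t = _table_from_arrays(x=rng.standard_normal(100), y=np.ones(100))
        fit = fit_study_model(t, ModelSpec("y", [Term("x")]))
        assert abs(fit.beta_hat["x"]) < 1e-10
        assert wald_test(fit, "x").T2 < 1e-6

    def test_collinear_terms_named_in_error(self, rng):
        x = rng.standard_normal(50)
        t = _table_from_arrays(x=x, y=rng.standard_normal(50))
        t.data["x2"] = 2.0 * x
        spec = ModelSpec("y", [Term("x"), Term("x2")])
        with pytest.raises(ValueError, match="collinear"):
            fit_study_model(t, spec)

    def test_missing_rows_dropped_and_counted(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        y[:5] = np.nan
        t = _table_from_arrays(x=x, y=y)
        fit = fit_study_model(t, ModelSpec("y", [Term("x")]))
        assert fit.n_dropped == 5
        assert fit.n_obs == 55

    def test_intercept_equivariance(self, cross_sectional_cohort, cs_spec):
        f0 = fit_study_model(cross_sectional_cohort, cs_spec)
        shifted = CohortTable(
            cross_sectional_cohort.data.assign(
                y=cross_sectional_cohort.data["y"] + 100.0
            ),
            design=CROSS_SECTIONAL,
            covariates=["x"],
            outcomes=["y"],
        )
        f1 = fit_study_model(shifted, cs_spec)
        assert abs(f1.beta_hat["Intercept"] - f0.beta_hat["Intercept"] - 100) < 1e-8
        np.testing.assert_allclose(
            f1.beta_hat.drop("Intercept"), f0.beta_hat.drop("Intercept"), atol=1e-8
        )

    def test_gee_one_obs_per_subject_matches_ols(self, cross_sectional_cohort):
        spec_cs = ModelSpec.from_formula("y ~ ns(age, df=2) + sex + x",
                                         design=CROSS_SECTIONAL)
        spec_ge = ModelSpec.from_formula("y ~ ns(age, df=2) + sex + x",
                                         design=LONGITUDINAL)
        f_ols = fit_study_model(cross_sectional_cohort, spec_cs)
        f_gee = fit_study_model(cross_sectional_cohort, spec_ge)
        np.testing.assert_allclose(
            f_gee.beta_hat, f_ols.beta_hat, rtol=1e-10, atol=1e-12
        )

    def test_n_subjects_vs_n_obs(self, longitudinal_cohort, long_spec):
        fit = fit_study_model(longitudinal_cohort, long_spec)
        assert fit.n_subjects < fit.n_obs
        assert fit.n_subjects == 400

    def test_gee_sandwich_se_matches_replicate_sd(self):
        """Clustered sandwich SE tracks the true sampling SD of the slope."""
        spec = ModelSpec.from_formula("y ~ x", design=LONGITUDINAL)
        betas, ses = [], []
        for s in range(300):
            cfg = SimConfig(
                n_subjects=150, visits_per_subject=3,
                beta_between=0.3, beta_within=0.3,
                subject_intercept_sd=1.0, residual_sd=1.0, seed=7000 + s,
            )
            t = simulate_longitudinal_study(cfg)
            fit = fit_study_model(t, spec)
            betas.append(fit.beta_hat["x"])
            ses.append(np.sqrt(fit.robust_cov.loc["x", "x"]))
        assert abs(np.mean(ses) / np.std(betas) - 1) < 0.15


class TestRobustCovarianceCalibration:
    def test_null_rejection_rate_under_heteroskedasticity(self, rng):
        """With variance depending on the covariate, the HC-sandwich Wald
        test still rejects a true null at close to the nominal 5% level."""
        spec = ModelSpec("y", [Term("x")])
        rejections = 0
        reps, n = 2000, 500
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = (0.5 + np.abs(x)) * rng.standard_normal(n)  # null: no mean effect
            t = _table_from_arrays(x=x, y=y)
            fit = fit_study_model(t, spec)
            rejections += fit.pvalues["x"] <= 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestWaldTest:
    def test_m_counts_spline_columns(self, cross_sectional_cohort, cs_spec):
        fit = fit_study_model(cross_sectional_cohort, cs_spec)
        assert wald_test(fit, "age").m == 2

    def test_beta0_at_estimate_gives_zero(self, cross_sectional_cohort, cs_spec):
        fit = fit_study_model(cross_sectional_cohort, cs_spec)
        b = fit.beta_hat.iloc[fit.term_index["x"]].to_numpy()
        w = wald_test(fit, "x", beta0=b)
        assert w.T2 == 0.0
        assert w.p == 1.0

    def test_unknown_term_raises(self, cross_sectional_cohort, cs_spec):
        fit = fit_study_model(cross_sectional_cohort, cs_spec)
        with pytest.raises(KeyError, match="unknown term"):
            wald_test(fit, "nope")


class TestBetweenWithin:
    def test_recovers_generating_coefficients(self):
        cfg = SimConfig(
            n_subjects=1500, visits_per_subject=3,
            beta_between=0.3, beta_within=0.3,
            covariate_between_sd=1.0, covariate_within_sd=0.6, seed=31,
        )
        t = simulate_longitudinal_study(cfg)
        spec = ModelSpec.from_formula("y ~ ns(age, df=2) + sex + x",
                                      design=LONGITUDINAL)
        bw = fit_between_within(t, "x", spec)
        assert abs(bw.beta_between - 0.3) < 3 * bw.se_between
        assert abs(bw.beta_within - 0.3) < 3 * bw.se_within
        assert bw.between_variance > 0
        assert bw.within_variance > 0

    def test_single_visit_table_raises(self, cross_sectional_cohort, long_spec):
        t = CohortTable(
            cross_sectional_cohort.data, design=LONGITUDINAL,
            covariates=["x"], outcomes=["y"],
        )
        with pytest.raises(ValueError, match="X_change"):
            fit_between_within(t, "x", long_spec)

    def test_requires_longitudinal_design(self, cross_sectional_cohort, cs_spec):
        with pytest.raises(ValueError, match="longitudinal"):
            fit_between_within(cross_sectional_cohort, "x", cs_spec)

    def test_single_effect_estimate_bracketed(self):
        """With unequal between/within effects the single-covariate GEE slope
        lies between them and moves toward the within effect as the
        within-subject covariate variance grows."""
        spec = ModelSpec.from_formula("y ~ x", design=LONGITUDINAL)
        slopes = {}
        for wsd in (0.4, 1.5):
            cfg = SimConfig(
                n_subjects=3000, visits_per_subject=3,
                beta_between=0.6, beta_within=0.1,
                covariate_between_sd=1.0, covariate_within_sd=wsd,
                subject_intercept_sd=0.5, seed=57,
            )
            t = simulate_longitudinal_study(cfg)
            slopes[wsd] = fit_study_model(t, spec).beta_hat["x"]
        for b in slopes.values():
            assert 0.1 - 0.03 <= b <= 0.6 + 0.03
        assert slopes[1.5] < slopes[0.4]  # pulled toward beta_within


class TestRemoveSiteEffects:
    def test_single_site_identity(self, cross_sectional_cohort, cs_spec):
        out = remove_site_effects(cross_sectional_cohort, cs_spec)
        pd.testing.assert_frame_equal(out.data, cross_sectional_cohort.data)

    def test_pure_additive_shifts_removed_exactly(self, cross_sectional_cohort, cs_spec):
        shifted = inject_site_effects(
            cross_sectional_cohort,
            SiteConfig(n_sites=4, additive_shift_sd=5.0),
            seed=9,
        )
        cleaned = remove_site_effects(shifted, cs_spec)
        # residualize for the covariates, then compare site means
        from bwasdesign.models import build_design_matrix

        X, _, _, _ = build_design_matrix(cleaned.data, cs_spec)
        y = cleaned.data["y"].to_numpy()
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        site_means = pd.Series(resid).groupby(cleaned.data["site_id"].values).mean()
        assert np.abs(site_means.to_numpy()).max() < 1e-8

    def test_no_site_effects_leaves_fit_unchanged(self, cross_sectional_cohort, cs_spec):
        relabeled = inject_site_effects(
            cross_sectional_cohort, SiteConfig(n_sites=4), seed=10
        )
        cleaned = remove_site_effects(relabeled, cs_spec)
        f0 = fit_study_model(relabeled, cs_spec)
        f1 = fit_study_model(cleaned, cs_spec)
        # only spurious site-mean noise is removed; slope moves < its SE/3
        se = np.sqrt(f0.robust_cov.loc["x", "x"])
        assert abs(f1.beta_hat["x"] - f0.beta_hat["x"]) < se / 3

    def test_missing_site_column_raises(self, cross_sectional_cohort, cs_spec):
        broken = cross_sectional_cohort.data.drop(columns=["site_id"])
        t = CohortTable.__new__(CohortTable)
        t.data = broken
        t.design = CROSS_SECTIONAL
        t.covariates = ["x"]
        t.outcomes = ["y"]
        with pytest.raises(ValueError, match="site"):
            remove_site_effects(t, cs_spec)
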