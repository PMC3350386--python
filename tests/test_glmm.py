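import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from psivar.cohort import cohort_from_flags
from psivar.errors import FitError, InputError
from psivar.glmm import (
    cluster_metric_ci,
    cluster_metrics,
    fit_random_intercept_logistic,
    median_odds_ratio,
    median_odds_ratio_inverse,
    model_sequence,
    rho,
    rho_inverse,
    table2_frame,
)
from psivar.riskadjust import build_design, fit_logistic
from psivar.synthetic import generate_discharges, generate_hospitals

from conftest import cohort_from_records, make_config


def toy_glmm_data(J=6, per=50, sigma2=0.36, beta0=-1.0, beta_x=0.8, seed=17):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(sigma2), J)
    rows = []
    for j in range(J):
        x = rng.normal(0, 1, per)
        p = 1.0 / (1.0 + np.exp(-(beta0 + beta_x * x + u[j])))
        ev = rng.random(per) < p
        rows += [
            {"hospital_id": f"H{j}", "x": xi, "event": int(e)}
            for xi, e in zip(x, ev)
        ]
    return pd.DataFrame(rows)


def exact_marginal_loglik(df, covariates, beta, sigma2):
    """Fine-grid per-hospital integration oracle (independent route)."""
    X, _ = build_design(df, covariates)
    y = df["event"].to_numpy(dtype=float)
    g = pd.factorize(df["hospital_id"], sort=True)[0]
    eta_fix = X @ beta
    total = 0.0
    half = 8 * np.sqrt(sigma2) + 2
    for j in range(g.max() + 1):
        m = g == j

        def integrand(b):
            eta = eta_fix[m] + b
            ll = np.sum(y[m] * eta - np.logaddexp(0.0, eta))
            return np.exp(ll - b * b / (2 * sigma2)) / np.sqrt(
                2 * np.pi * sigma2
            )

        val, _ = quad(integrand, -half, half, limit=400)
        total += np.log(val)
    return total


class TestFitRandomInterceptLogistic:
    def test_degenerate_reduction_to_irls(self):
        df = toy_glmm_data()
        glmm0 = fit_random_intercept_logistic(df, ["x"], sigma2_fixed=0.0)
        irls = fit_logistic(df, ["x"])
        diff = np.max(
            np.abs(glmm0.fixed_effects.to_numpy() - irls.coefficients.to_numpy())
        )
        assert diff < 1e-6
        assert glmm0.sigma2_hospital == 0.0

    def test_laplace_matches_fine_grid_integration(self):
        df = toy_glmm_data()
        fit = fit_random_intercept_logistic(df, ["x"])
        exact = exact_marginal_loglik(
            df, ["x"], fit.fixed_effects.to_numpy(), fit.sigma2_hospital
        )
        assert abs(exact - fit.log_likelihood) / abs(exact) < 1e-3

    def test_agq_matches_fine_grid_integration_absolutely(self):
        df = toy_glmm_data()
        fit = fit_random_intercept_logistic(
            df, ["x"], method="agq", n_quad=15, compute_se=False
        )
        exact = exact_marginal_loglik(
            df, ["x"], fit.fixed_effects.to_numpy(), fit.sigma2_hospital
        )
        assert abs(exact - fit.log_likelihood) < 1e-3

    def test_parameter_recovery_small(self):
        sigma2 = 0.38
        cfg = make_config(
            n_hospitals=50,
            hospital_size_mean=400.0,
            hospital_size_dispersion=6.0,
            sigma2_hospital=sigma2,
            beta={"intercept": -3.2, "age": 0.0, "sex": 0.2},
            seed=31,
        )
        h = generate_hospitals(cfg)
        d = generate_discharges(h, cfg)
        cohort = cohort_from_flags(d, "psi", hospital_attrs=h)
        fit = fit_random_intercept_logistic(cohort, ["sex"])
        assert fit.converged
        assert abs(fit.sigma2_hospital - sigma2) < 3 * fit.sigma2_se

    def test_laplace_vs_agq_within_five_percent(self):
        df = toy_glmm_data(J=8, per=60, seed=4)
        lap = fit_random_intercept_logistic(df, ["x"], compute_se=False)
        agq = fit_random_intercept_logistic(
            df, ["x"], method="agq", n_quad=25, compute_se=False
        )
        assert abs(lap.sigma2_hospital - agq.sigma2_hospital) < 0.05 * max(
            lap.sigma2_hospital, 0.01
        )

    def test_fixed_effects_match_glm_on_null_data(self):
        df = toy_glmm_data(J=10, per=80, sigma2=0.0, seed=9)
        glmm = fit_random_intercept_logistic(df, ["x"], compute_se=False)
        glm = fit_logistic(df, ["x"])
        for name in ["intercept", "x"]:
            assert (
                abs(glmm.fixed_effects[name] - glm.coefficients[name])
                < 3 * glm.se[name]
            )

    def test_boundary_reported_on_homogeneous_data(self):
        df = toy_glmm_data(J=10, per=60, sigma2=0.0, seed=3)
        fit = fit_random_intercept_logistic(df, ["x"], compute_se=False)
        assert fit.sigma2_hospital < 0.05

    def test_single_hospital_rejected(self):
        df = toy_glmm_data(J=1)
        with pytest.raises(InputError):
            fit_random_intercept_logistic(df, ["x"])

    def test_events_in_one_hospital_rejected(self):
        df = toy_glmm_data(J=4, per=20, seed=8)
        df.loc[df["hospital_id"] != "H0", "event"] = 0
        with pytest.raises(FitError):
            fit_random_intercept_logistic(df, ["x"])


class TestModelSequence:
    def test_quasi_sentinel_gets_one_model(self, small_config):
        h = generate_hospitals(small_config)
        d = generate_discharges(h, small_config)
        cohort = cohort_from_flags(
            d, "psi", hospital_attrs=h, is_quasi_sentinel=True
        )
        fits = model_sequence(cohort, [], compute_se=False)
        assert len(fits) == 1
        assert fits[0].covariates == ()

    def test_three_nested_models(self, small_cohort):
        fits = model_sequence(small_cohort, [], compute_se=False)
        assert len(fits) == 3
        assert fits[1].covariates == ("age", "sex")

    def test_null_covariates_leave_sigma2_stable(self):
        cfg = make_config(
            n_hospitals=40,
            hospital_size_mean=400.0,
            sigma2_hospital=0.3,
            beta={"intercept": -3.0, "age": 0.0, "sex": 0.0, "cm": 0.0},
            comorbidity_prevalences={"cm": 0.2},
            seed=13,
        )
        h = generate_hospitals(cfg)
        d = generate_discharges(h, cfg)
        cohort = cohort_from_flags(d, "psi", hospital_attrs=h)
        fits = model_sequence(cohort, ["cm"], compute_se=False)
        s1, s3 = fits[0].sigma2_hospital, fits[2].sigma2_hospital
        assert abs(s3 - s1) < 0.5 * s1

    def test_confounded_covariate_reduces_sigma2(self, rng):
        # case-mix clustering: comorbidity prevalence varies by hospital,
        # outcome risk depends only on the comorbidity
        rows = []
        for j in range(30):
            prev = 1.0 / (1.0 + np.exp(-(-1.2 + rng.normal(0, 1.2))))
            cm = rng.random(400) < prev
            p = 1.0 / (1.0 + np.exp(-(-3.0 + 1.6 * cm)))
            ev = rng.random(400) < p
            age = rng.normal(65, 10, 400)
            sex = rng.choice(["female", "male"], 400)
            rows += [
                {"hospital_id": f"H{j:02d}", "age": a, "sex": s,
                 "cm": int(c), "event": int(e)}
                for a, s, c, e in zip(age, sex, cm, ev)
            ]
        cohort = cohort_from_records(pd.DataFrame(rows))
        fits = model_sequence(cohort, ["cm"], compute_se=False)
        assert fits[2].sigma2_hospital < fits[0].sigma2_hospital


class TestClusterMetrics:
    def test_rho_printed_value(self):
        assert round(rho(0.20), 2) == 0.06

    def test_rho_trivial_values(self):
        assert rho(0.0) == 0.0
        assert rho(np.pi**2 / 3) == pytest.approx(0.5, abs=1e-12)

    def test_mor_printed_value(self):
        assert round(median_odds_ratio(0.20), 2) == 1.53

    def test_mor_at_zero_is_one(self):
        assert median_odds_ratio(0.0) == 1.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rho(-0.1)
        with pytest.raises(ValueError):
            median_odds_ratio(-0.1)

    def test_mor_pairwise_simulation_oracle(self):
        # definition: median OR between two random hospitals for identical
        # patients = median of exp(|u1 - u2|), u ~ N(0, sigma2)
        sigma2 = 1.05
        rng = np.random.default_rng(0)
        u1 = rng.normal(0, np.sqrt(sigma2), 100_000)
        u2 = rng.normal(0, np.sqrt(sigma2), 100_000)
        empirical = np.median(np.exp(np.abs(u1 - u2)))
        assert empirical == pytest.approx(median_odds_ratio(sigma2), abs=0.03)

    @given(st.floats(min_value=1e-6, max_value=20.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_inversion(self, sigma2):
        assert rho_inverse(rho(sigma2)) == pytest.approx(sigma2, rel=1e-10)
        assert median_odds_ratio_inverse(
            median_odds_ratio(sigma2)
        ) == pytest.approx(sigma2, rel=1e-10)

    @given(
        st.floats(min_value=1e-4, max_value=10.0),
        st.floats(min_value=1e-4, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert rho(lo) < rho(hi)
        assert median_odds_ratio(lo) < median_odds_ratio(hi)


@pytest.fixture(scope="module")
def fitted():
    df = toy_glmm_data(J=25, per=120, sigma2=0.4, seed=23)
    return fit_random_intercept_logistic(df, ["x"])


class TestClusterMetricCI:
    def test_ci_is_monotone_transform_of_sigma2_ci(self, fitted):
        lo, hi = fitted.sigma2_ci
        assert cluster_metric_ci(fitted, "rho") == (rho(lo), rho(hi))
        assert cluster_metric_ci(fitted, "mor") == (
            median_odds_ratio(lo),
            median_odds_ratio(hi),
        )

    def test_point_inside_ci(self, fitted):
        m = cluster_metrics(fitted)
        assert m.rho_ci[0] <= m.rho <= m.rho_ci[1]
        assert m.mor_ci[0] <= m.mor <= m.mor_ci[1]

    def test_boundary_interval_pinned_at_null(self):
        df = toy_glmm_data(J=10, per=40, sigma2=0.0, seed=2)
        fit = fit_random_intercept_logistic(df, ["x"], sigma2_fixed=0.0)
        assert cluster_metric_ci(fit, "rho")[0] == 0.0
        assert cluster_metric_ci(fit, "mor")[0] == 1.0

    def test_sigma2_ci_coverage(self):
        # reduced-scale coverage check of the log-scale Wald interval
        sigma2 = 0.3
        cover = 0
        n_rep = 25
        for r in range(n_rep):
            df = toy_glmm_data(J=40, per=60, sigma2=sigma2, beta0=-2.0,
                               seed=300 + r)
            fit = fit_random_intercept_logistic(df, ["x"])
            lo, hi = fit.sigma2_ci
            cover += lo <= sigma2 <= hi
        # 3 MC SEs around 95% at 25 replicates
        assert cover / n_rep >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / n_rep)


def test_table2_frame_shape():
    df = toy_glmm_data(J=12, per=60, seed=5)
    df["age"] = np.random.default_rng(1).normal(60, 10, len(df))
    df["sex"] = np.random.default_rng(2).choice(["female", "male"], len(df))
    cohort = cohort_from_records(df)
    fits = model_sequence(cohort, ["x"])
    tab = table2_frame(fits)
    assert list(tab.columns) == ["model_1", "model_2", "model_3"]
    for row in ("hospital_variance", "rho", "mor", "intercept"):
        assert row in tab.index
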