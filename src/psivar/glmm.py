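"""Two-level random-intercept logistic regression and cluster metrics.

Patients are nested in hospitals; the hospital effect is a Gaussian random
intercept on the log-odds scale.  The marginal likelihood integrates the
hospital effect out per cluster:

    L_j(beta, sigma2) = \\int prod_i Bernoulli(y_ij; inv_logit(x_ij' beta + b))
                        N(b; 0, sigma2) db

approximated by a Laplace expansion around the per-hospital posterior mode
(default) or by adaptive Gauss–Hermite quadrature centred and scaled at that
mode.  The inner mode solves are vectorised across hospitals with
``np.bincount``, so each likelihood evaluation is linear in the number of
records.  The outer optimisation runs in ``(beta, log sigma2)``; the lower
bound on ``log sigma2`` is the variance boundary.

Cluster metrics derived from ``sigma2``:

* ``rho``: latent-variable intraclass correlation
  ``sigma2 / (sigma2 + pi^2/3)``, the share of latent outcome variance at
  the hospital level (logistic individual variance ``pi^2/3``);
* ``median_odds_ratio``: ``exp(sqrt(2 sigma2) * z_0.75)`` — the median
  odds ratio between the higher- and lower-risk hospital for two identical
  patients in two randomly chosen hospitals.

Confidence intervals for both are monotone transforms of a Wald interval
for ``log sigma2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .cohort import Cohort
from .errors import ConvergenceError, FitError, InputError, SeparationError
from .riskadjust import SEPARATION_BOUND, build_design, fit_logistic

__all__ = [
    "GlmmFit",
    "ClusterMetrics",
    "fit_random_intercept_logistic",
    "model_sequence",
    "rho",
    "rho_inverse",
    "median_odds_ratio",
    "median_odds_ratio_inverse",
    "cluster_metric_ci",
    "cluster_metrics",
    "table2_frame",
]

log = logging.getLogger(__name__)

INDIVIDUAL_VARIANCE = np.pi**2 / 3.0

_LOG_S2_MIN = np.log(1e-8)
_LOG_S2_MAX = np.log(25.0)


@dataclass
class GlmmFit:
    """Converged random-intercept logistic fit plus conditional modes."""

    fixed_effects: pd.Series
    fixed_se: pd.Series
    sigma2_hospital: float
    sigma2_se: float
    sigma2_ci: tuple
    log_sigma2_se: float
    log_likelihood: float
    method: str
    n_quad: int
    converged: bool
    boundary: bool
    n_obs: int
    hospital_ids: pd.Index
    b_hat: np.ndarray          # conditional posterior modes, fit order
    b_sd: np.ndarray           # conditional curvature SDs at the modes
    covariates: tuple = ()
    n_iter: int = 0
    dropped: tuple = ()

    @property
    def n_hospitals(self) -> int:
        return len(self.hospital_ids)


@dataclass(frozen=True)
class ClusterMetrics:
    rho: float
    rho_ci: tuple
    mor: float
    mor_ci: tuple
    individual_variance: float = INDIVIDUAL_VARIANCE


def rho(sigma2: float) -> float:
    """Latent-variable ICC: sigma2 / (sigma2 + pi^2/3)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    return float(sigma2 / (sigma2 + INDIVIDUAL_VARIANCE))


def rho_inverse(r: float) -> float:
    if not 0 <= r < 1:
        raise ValueError("rho must lie in [0, 1)")
    return float(r * INDIVIDUAL_VARIANCE / (1.0 - r))


def median_odds_ratio(sigma2: float) -> float:
    """exp(sqrt(2 sigma2) * Phi^-1(0.75))."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    return float(np.exp(np.sqrt(2.0 * sigma2) * norm.ppf(0.75)))


def median_odds_ratio_inverse(m: float) -> float:
    if m < 1:
        raise ValueError("MOR must be >= 1")
    return float((np.log(m) / norm.ppf(0.75)) ** 2 / 2.0)


class _LaplaceObjective:
    """Negative approximate marginal log-likelihood in (beta, log sigma2).

    Keeps the latest conditional modes as a warm start; inner Newton is
    safeguarded with step capping and runs to a 1e-10 step tolerance so the
    outer finite-difference gradients stay clean.
    """

    def __init__(self, X, y, groups, method="laplace", n_quad=9):
        self.X = X
        self.y = y
        self.g = groups
        self.J = int(groups.max()) + 1
        self.method = method
        if method == "agq":
            t, w = np.polynomial.hermite.hermgauss(n_quad)
            self.t, self.logw = t, np.log(w)
        self.n_quad = n_quad
        self.b_warm = np.zeros(self.J)

    def _modes(self, eta_fix, sigma2, tol=1e-10, max_iter=100):
        b = self.b_warm.copy()
        g = self.g
        for _ in range(max_iter):
            eta = eta_fix + b[g]
            p = expit(eta)
            grad = np.bincount(g, weights=self.y - p, minlength=self.J) - b / sigma2
            hess = np.bincount(g, weights=p * (1 - p), minlength=self.J) + 1.0 / sigma2
            step = np.clip(grad / hess, -4.0, 4.0)
            b += step
            if np.max(np.abs(step)) < tol:
                break
        eta = eta_fix + b[g]
        p = expit(eta)
        hess = np.bincount(g, weights=p * (1 - p), minlength=self.J) + 1.0 / sigma2
        self.b_warm = b.copy()
        return b, hess

    def _data_loglik_by_group(self, eta):
        ll = self.y * eta - np.logaddexp(0.0, eta)
        return np.bincount(self.g, weights=ll, minlength=self.J)

    def loglik(self, beta, sigma2):
        eta_fix = self.X @ beta
        b, hess = self._modes(eta_fix, sigma2)
        if self.method == "laplace":
            ll_data = self._data_loglik_by_group(eta_fix + b[self.g])
            per_group = (
                ll_data
                - b**2 / (2.0 * sigma2)
                - 0.5 * np.log(sigma2)
                - 0.5 * np.log(hess)
            )
            return float(per_group.sum()), b, hess
        # adaptive Gauss-Hermite centred at the mode, scaled by curvature
        tau = 1.0 / np.sqrt(hess)
        vals = np.empty((self.J, self.n_quad))
        for k in range(self.n_quad):
            bk = b + np.sqrt(2.0) * tau * self.t[k]
            h = (
                self._data_loglik_by_group(eta_fix + bk[self.g])
                - bk**2 / (2.0 * sigma2)
            )
            vals[:, k] = self.logw[k] + self.t[k] ** 2 + h
        per_group = (
            logsumexp(vals, axis=1)
            + 0.5 * np.log(2.0)
            + np.log(tau)
            - 0.5 * np.log(2.0 * np.pi * sigma2)
        )
        return float(per_group.sum()), b, hess

    def __call__(self, params):
        beta = params[:-1]
        sigma2 = float(np.exp(params[-1]))
        ll, _, _ = self.loglik(beta, sigma2)
        return -ll


def _central_gradient(f, x, eps):
    g = np.empty_like(x)
    for i in range(x.size):
        step = np.zeros_like(x)
        step[i] = eps[i]
        g[i] = (f(x + step) - f(x - step)) / (2.0 * eps[i])
    return g


def _num_hessian(f, x, eps):
    p = x.size
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = eps[i]
        for j in range(i, p):
            ej = np.zeros(p)
            ej[j] = eps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / eps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * eps[i] * eps[j])
    return H


def fit_random_intercept_logistic(
    cohort: Cohort | pd.DataFrame,
    covariates: list[str] = (),
    method: str = "laplace",
    n_quad: int = 9,
    sigma2_fixed: float | None = None,
    compute_se: bool = True,
    alpha: float = 0.05,
) -> GlmmFit:
    """Fit the 2-level random-intercept logistic model.

    ``covariates`` are patient-level fixed effects (an intercept is always
    included).  ``sigma2_fixed`` clamps the variance (0 reduces the model to
    ordinary logistic regression, useful for checks).  ``compute_se=False``
    skips the numerical Hessian when only point estimates and conditional
    modes are needed (e.g. for profiling large simulations).
    """
    records = cohort.records if isinstance(cohort, Cohort) else cohort
    if "hospital_id" not in records.columns:
        raise InputError("records lack 'hospital_id'")
    codes, hospital_ids = pd.factorize(records["hospital_id"], sort=True)
    if len(hospital_ids) < 2:
        raise InputError("need at least 2 hospitals")
    y = records["event"].to_numpy(dtype=float)
    events_per_hosp = np.bincount(codes, weights=y)
    if (events_per_hosp > 0).sum() < 2:
        raise FitError("events present in fewer than 2 hospitals")

    X, names = build_design(records, list(covariates))
    dropped = []
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            dropped.append(names[j])
            log.warning("dropping constant covariate '%s'", names[j])
        else:
            keep.append(j)
    X = X[:, keep]
    names = [names[j] for j in keep]

    # centre age for conditioning (reported uncentred, see below)
    age_mean = 0.0
    if "age" in names:
        ai = names.index("age")
        age_mean = float(X[:, ai].mean())
        X = X.copy()
        X[:, ai] -= age_mean

    obj = _LaplaceObjective(X, y, codes, method=method, n_quad=n_quad)

    # warm-start fixed effects at the ordinary logistic solution
    glm = fit_logistic(records.assign(), [n for n in names if n != "intercept"])
    beta0 = glm.coefficients.reindex(names).fillna(0.0).to_numpy().copy()
    if "age" in names:
        beta0[0] += beta0[names.index("age")] * age_mean  # re-centre intercept

    if sigma2_fixed is not None:
        if sigma2_fixed < 0:
            raise ValueError("sigma2_fixed must be >= 0")
        if sigma2_fixed == 0.0:
            # exact degenerate reduction: ordinary logistic fit (uncentred)
            fit0 = glm
            return GlmmFit(
                fixed_effects=fit0.coefficients.reindex(names),
                fixed_se=fit0.se.reindex(names),
                sigma2_hospital=0.0, sigma2_se=float("nan"),
                sigma2_ci=(0.0, 0.0), log_sigma2_se=float("nan"),
                log_likelihood=fit0.log_likelihood, method=method,
                n_quad=n_quad, converged=fit0.converged, boundary=True,
                n_obs=len(y), hospital_ids=pd.Index(hospital_ids),
                b_hat=np.zeros(len(hospital_ids)),
                b_sd=np.zeros(len(hospital_ids)),
                covariates=tuple(covariates), dropped=tuple(dropped),
            )
        nll = lambda bet: obj(np.append(bet, np.log(sigma2_fixed)))
        res = minimize(nll, beta0, method="L-BFGS-B",
                       options={"ftol": 1e-13, "gtol": 1e-8})
        params = np.append(res.x, np.log(sigma2_fixed))
    else:
        x0 = np.append(beta0, np.log(0.1))
        res = minimize(
            obj,
            x0,
            method="L-BFGS-B",
            jac="3-point",
            bounds=[(None, None)] * len(names) + [(_LOG_S2_MIN, _LOG_S2_MAX)],
            options={"ftol": 1e-13, "gtol": 1e-7, "maxiter": 500},
        )
        params = res.x.copy()

    def _active(params):
        at_bound = (
            sigma2_fixed is None and params[-1] <= _LOG_S2_MIN + 1e-9
        )
        if sigma2_fixed is not None or at_bound:
            return slice(0, len(names)), at_bound
        return slice(0, len(names) + 1), at_bound

    # Newton polish: L-BFGS-B stops on ftol before the gradient criterion
    # on large data, so finish with full Newton steps on the active block.
    eps = np.full(params.size, 1e-5)
    converged = False
    for _ in range(6):
        act, boundary = _active(params)
        grad_scale = 1e-6 * max(1.0, abs(float(obj(params))))
        grad = _central_gradient(obj, params, eps)
        if float(np.max(np.abs(grad[act]))) < grad_scale:
            converged = True
            break
        try:
            H = _num_hessian(obj, params, eps)[act, act]
            step = np.linalg.solve(H, grad[act])
        except np.linalg.LinAlgError:
            break
        params[act] -= np.clip(step, -1.0, 1.0)
        if sigma2_fixed is None:
            params[-1] = np.clip(params[-1], _LOG_S2_MIN, _LOG_S2_MAX)
    act, boundary = _active(params)
    if not converged:
        log.warning(
            "GLMM convergence check failed after polish (%s)", res.message
        )

    beta_c = params[: len(names)]
    theta = params[-1]
    sigma2 = float(sigma2_fixed) if sigma2_fixed is not None else float(
        np.exp(theta)
    )
    if boundary:
        sigma2 = 0.0

    over = np.abs(beta_c[1:]) > SEPARATION_BOUND
    if over.any():
        bad = [names[1 + i] for i in np.flatnonzero(over)]
        raise SeparationError(f"perfect separation suspected for: {bad}")

    ll, b_hat, hess = obj.loglik(beta_c, max(sigma2, 1e-8))

    # covariance of (beta, log sigma2) by numerical Hessian
    se_theta = float("nan")
    cov_beta = None
    if compute_se and not boundary:
        H = _num_hessian(obj, params, eps)[act, act]
        try:
            cov = np.linalg.inv(H)
            cov_beta = cov[: len(names), : len(names)]
            if sigma2_fixed is None:
                se_theta = float(np.sqrt(max(cov[-1, -1], 0.0)))
        except np.linalg.LinAlgError:
            log.warning("singular Hessian; SEs unavailable")

    if cov_beta is not None:
        beta_u, se_u = _uncentre(beta_c, cov_beta, names, age_mean)
    else:
        T = np.eye(len(names))
        if "age" in names and age_mean != 0.0:
            T[0, names.index("age")] = -age_mean
        beta_u = T @ beta_c
        se_u = np.full(len(names), np.nan)

    z = norm.ppf(1 - alpha / 2)
    if boundary:
        sigma2_ci = (0.0, float("nan"))
        sigma2_se = float("nan")
        log.warning("sigma2 at the 0 boundary: one-sided interval")
    elif np.isfinite(se_theta):
        sigma2_ci = (
            float(np.exp(theta - z * se_theta)),
            float(np.exp(theta + z * se_theta)),
        )
        sigma2_se = float(sigma2 * se_theta)  # delta method
    else:
        sigma2_ci = (float("nan"), float("nan"))
        sigma2_se = float("nan")

    return GlmmFit(
        fixed_effects=pd.Series(beta_u, index=names),
        fixed_se=pd.Series(se_u, index=names),
        sigma2_hospital=sigma2,
        sigma2_se=sigma2_se,
        sigma2_ci=sigma2_ci,
        log_sigma2_se=float(se_theta),
        log_likelihood=ll,
        method=method,
        n_quad=n_quad,
        converged=converged,
        boundary=bool(boundary),
        n_obs=len(y),
        hospital_ids=pd.Index(hospital_ids),
        b_hat=b_hat,
        b_sd=1.0 / np.sqrt(hess),
        covariates=tuple(covariates),
        n_iter=int(res.nit),
        dropped=tuple(dropped),
    )


def _uncentre(beta_c, cov_c, names, age_mean):
    T = np.eye(len(names))
    if "age" in names and age_mean != 0.0:
        T[0, names.index("age")] = -age_mean
    beta = T @ beta_c
    cov = T @ cov_c @ T.T
    return beta, np.sqrt(np.clip(np.diag(cov), 0.0, None))


def model_sequence(
    cohort: Cohort,
    screened_covariates: list[str],
    method: str = "laplace",
    n_quad: int = 9,
    compute_se: bool = True,
) -> list[GlmmFit]:
    """Nested fits: random intercept only; + age/sex; + comorbidities.

    A quasi-sentinel cohort gets only the intercept model (no patient-level
    adjustment).
    """
    fits = [
        fit_random_intercept_logistic(
            cohort, [], method=method, n_quad=n_quad, compute_se=compute_se
        )
    ]
    if cohort.is_quasi_sentinel:
        return fits
    fits.append(
        fit_random_intercept_logistic(
            cohort, ["age", "sex"], method=method, n_quad=n_quad,
            compute_se=compute_se,
        )
    )
    fits.append(
        fit_random_intercept_logistic(
            cohort, ["age", "sex"] + list(screened_covariates),
            method=method, n_quad=n_quad, compute_se=compute_se,
        )
    )
    return fits


def cluster_metric_ci(fit: GlmmFit, metric: str, alpha: float = 0.05) -> tuple:
    """CI for rho or MOR by monotone transform of the log-sigma2 Wald CI."""
    func = {"rho": rho, "mor": median_odds_ratio}[metric]
    if fit.boundary or fit.sigma2_hospital == 0.0:
        log.warning("sigma2 at boundary: lower CI endpoint pinned at the null")
        return (func(0.0), float("nan"))
    if not fit.converged or not np.isfinite(fit.log_sigma2_se):
        raise FitError("need a converged fit with a finite sigma2 SE")
    lo, hi = fit.sigma2_ci
    return (func(lo), func(hi))


def cluster_metrics(fit: GlmmFit, alpha: float = 0.05) -> ClusterMetrics:
    s2 = fit.sigma2_hospital
    return ClusterMetrics(
        rho=rho(s2),
        rho_ci=cluster_metric_ci(fit, "rho", alpha=alpha),
        mor=median_odds_ratio(s2),
        mor_ci=cluster_metric_ci(fit, "mor", alpha=alpha),
    )


def table2_frame(fits: list[GlmmFit], alpha: float = 0.05) -> pd.DataFrame:
    """Side-by-side model summary: ORs, hospital variance, rho, MOR."""
    z = norm.ppf(1 - alpha / 2)
    columns = {}
    all_covs = []
    for f in fits:
        for name in f.fixed_effects.index:
            if name not in all_covs:
                all_covs.append(name)
    for m, f in enumerate(fits, start=1):
        col = {}
        for name in all_covs:
            if name in f.fixed_effects.index:
                b = f.fixed_effects[name]
                se = f.fixed_se[name]
                col[name] = (
                    f"{np.exp(b):.4g} ({np.exp(b - z * se):.4g} to "
                    f"{np.exp(b + z * se):.4g})"
                    if np.isfinite(se)
                    else f"{np.exp(b):.4g}"
                )
            else:
                col[name] = ""
        s2 = f.sigma2_hospital
        lo, hi = f.sigma2_ci
        col["hospital_variance"] = (
            f"{s2:.3g} ({lo:.3g} to {hi:.3g})"
            if np.isfinite(hi)
            else f"{s2:.3g} (SE {f.sigma2_se:.3g})"
            if np.isfinite(f.sigma2_se)
            else f"{s2:.3g}"
        )
        try:
            cm = cluster_metrics(f, alpha=alpha)
            col["rho"] = f"{cm.rho:.3g} ({cm.rho_ci[0]:.3g} to {cm.rho_ci[1]:.3g})"
            col["mor"] = f"{cm.mor:.3g} ({cm.mor_ci[0]:.3g} to {cm.mor_ci[1]:.3g})"
        except FitError:
            col["rho"] = f"{rho(s2):.3g}"
            col["mor"] = f"{median_odds_ratio(s2):.3g}"
        columns[f"model_{m}"] = col
    return pd.DataFrame(columns)
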