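"""Systematic-variation statistics on hospital-level counts.

Two families of measures are provided:

* percentile ratios of hospital rates (``RV`` ratios), a scale-free spread
  measure computed with linear-interpolation percentiles; and
* the variance of hospital log relative risks under a Poisson–lognormal
  hierarchical model — ``y_j | r_j ~ Poisson(e_j r_j)`` with
  ``log r_j ~ N(mu, sigma2)`` — estimated by marginal maximum likelihood
  with Gauss–Hermite quadrature.  The estimated ``sigma2`` is the
  "systematic variation" statistic: 0 means all between-hospital spread is
  compatible with Poisson noise.

Uncertainty comes from a nonparametric cluster bootstrap that resamples
hospitals with replacement and reports percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .errors import ConvergenceError, FitError, InputError

__all__ = [
    "PoissonLogNormalModel",
    "EstimateCI",
    "VariationReport",
    "ratio_of_variation",
    "fit_poisson_lognormal",
    "bootstrap_percentile_ci",
    "variation_report",
    "mean_centred_log_incidence",
]

log = logging.getLogger(__name__)

_SIGMA2_FLOOR = 1e-8
_SIGMA2_CEIL = 50.0


@dataclass(frozen=True)
class PoissonLogNormalModel:
    mu: float
    sigma2: float
    log_marginal_likelihood: float
    n_quadrature: int
    converged: bool
    boundary: bool


@dataclass(frozen=True)
class EstimateCI:
    point: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.lo <= self.hi):
            raise ValueError("interval bounds out of order")


@dataclass(frozen=True)
class VariationReport:
    rv_95_5: EstimateCI
    rv_75_25: EstimateCI
    eb: EstimateCI
    n_hospitals: int
    bootstrap_reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("rv_95_5", self.rv_95_5),
            ("rv_75_25", self.rv_75_25),
            ("eb", self.eb),
        ]
        return pd.DataFrame(
            {
                "statistic": [r[0] for r in rows],
                "point": [r[1].point for r in rows],
                "lo": [r[1].lo for r in rows],
                "hi": [r[1].hi for r in rows],
                "reps": self.bootstrap_reps,
                "seed": self.seed,
            }
        )


def ratio_of_variation(
    rates,
    hi: float = 95.0,
    lo: float = 5.0,
    zero_policy: str = "error",
) -> float:
    """Ratio of the hi-th to the lo-th percentile of hospital rates.

    Percentiles use linear interpolation.  A zero lo-percentile is an error
    by default; ``zero_policy="truncate"`` replaces zero rates with the
    smallest nonzero rate before taking percentiles.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0 or np.any(rates < 0):
        raise InputError("rates must be a nonempty vector of nonnegative reals")
    if not 0 <= lo < hi <= 100:
        raise ValueError("need 0 <= lo < hi <= 100")
    if zero_policy == "truncate" and np.any(rates == 0):
        nonzero = rates[rates > 0]
        if nonzero.size == 0:
            raise InputError("all rates are zero")
        rates = np.maximum(rates, nonzero.min())
    p_hi, p_lo = np.percentile(rates, [hi, lo], method="linear")
    if p_lo == 0:
        raise InputError(
            f"P{lo:g} of the rates is 0; set zero_policy='truncate' to "
            "replace zeros with the smallest nonzero rate, or drop them "
            "explicitly before calling"
        )
    return float(p_hi / p_lo)


class _PlnObjective:
    """Negative marginal log-likelihood in (mu, log sigma2), with gradient.

    The per-unit integral uses *adaptive* Gauss–Hermite quadrature: nodes
    are centred at the unit's posterior mode ``b_j`` of

        f_j(b) = y_j b - e_j e^b - (b - mu)^2 / (2 sigma2)

    and scaled by the curvature there, so the rule stays accurate when the
    Poisson likelihood is much narrower than the prior (large ``e_j``).
    Gradients come from the Fisher identity
    ``d log L / d eta = E_posterior[d log joint / d eta]`` evaluated on the
    same nodes.
    """

    def __init__(self, y, e, n_quadrature):
        self.y = np.asarray(y, dtype=float)
        self.e = np.asarray(e, dtype=float)
        t, w = np.polynomial.hermite.hermgauss(n_quadrature)
        self.t = t[None, :]                       # (1, K)
        self.logw_t2 = (np.log(w) + t**2)[None, :]
        self.const = float(-np.sum(gammaln(self.y + 1)))
        self.b_warm = np.log((self.y + 0.5) / self.e)

    def _modes(self, mu, sigma2, tol=1e-12, max_iter=50):
        b = self.b_warm.copy()
        for _ in range(max_iter):
            lam = self.e * np.exp(b)
            grad = self.y - lam - (b - mu) / sigma2
            hess = lam + 1.0 / sigma2
            step = np.clip(grad / hess, -2.0, 2.0)
            b += step
            if np.max(np.abs(step)) < tol:
                break
        self.b_warm = b.copy()
        hess = self.e * np.exp(b) + 1.0 / sigma2
        return b, hess

    def value_grad(self, mu, sigma2):
        b_hat, hess = self._modes(mu, sigma2)
        tau = 1.0 / np.sqrt(hess)
        z = b_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.t  # (J, K)
        f = (
            self.y[:, None] * z
            - self.e[:, None] * np.exp(z)
            - (z - mu) ** 2 / (2.0 * sigma2)
        )
        a = self.logw_t2 + f
        lse = logsumexp(a, axis=1)
        per_unit = lse + 0.5 * np.log(2.0) + np.log(tau) - 0.5 * np.log(
            2.0 * np.pi * sigma2
        )
        ll = float(per_unit.sum()) + self.const
        p = np.exp(a - lse[:, None])  # posterior node weights per unit
        dev = z - mu
        d_mu = float(np.sum(p * dev) / sigma2)
        d_s2 = float(np.sum(p * (dev**2 / sigma2 - 1.0)) / (2.0 * sigma2))
        return ll, d_mu, d_s2

    def __call__(self, params):
        mu, theta = params
        sigma2 = float(np.exp(theta))
        ll, d_mu, d_s2 = self.value_grad(mu, sigma2)
        return -ll, -np.array([d_mu, d_s2 * sigma2])


def fit_poisson_lognormal(
    y,
    e,
    n_quadrature: int = 30,
) -> PoissonLogNormalModel:
    """Marginal-ML fit of the Poisson–lognormal hospital-count model.

    ``sigma2 >= 0`` is enforced through a log parameterisation with a lower
    bound acting as the boundary; fits pinned there report ``sigma2 = 0``
    with ``boundary=True``.  All-zero counts short-circuit to the boundary.
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    if y.shape != e.shape or y.ndim != 1:
        raise InputError("y and e must be 1-d vectors of equal length")
    if y.size < 5:
        raise InputError("need at least 5 units")
    if np.any(e <= 0):
        raise InputError("expected counts must all be > 0")
    if np.any(y < 0):
        raise InputError("counts must be nonnegative")

    if y.sum() == 0:
        mu = float(np.log(0.5 / e.sum()))  # continuity-corrected pooled rate
        obj = _PlnObjective(y, e, n_quadrature)
        nll, _ = obj(np.array([mu, np.log(_SIGMA2_FLOOR)]))
        log.warning("all counts are zero: sigma2 reported at the 0 boundary")
        return PoissonLogNormalModel(
            mu=mu, sigma2=0.0, log_marginal_likelihood=-nll,
            n_quadrature=n_quadrature, converged=True, boundary=True,
        )

    obj = _PlnObjective(y, e, n_quadrature)
    log_rr = np.log((y + 0.5) / e)
    v0 = np.clip(np.var(log_rr) - np.mean(1.0 / (y + 0.5)), 1e-4, _SIGMA2_CEIL / 2)
    mu0 = float(np.log(y.sum() / e.sum()) - v0 / 2.0)
    res = minimize(
        obj,
        x0=np.array([mu0, np.log(v0)]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None), (np.log(_SIGMA2_FLOOR), np.log(_SIGMA2_CEIL))],
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        raise ConvergenceError(
            f"Poisson-lognormal fit failed: {res.message} (grad={res.jac})"
        )
    mu, theta = res.x
    boundary = theta <= np.log(_SIGMA2_FLOOR) + 1e-9
    sigma2 = 0.0 if boundary else float(np.exp(theta))
    return PoissonLogNormalModel(
        mu=float(mu),
        sigma2=sigma2,
        log_marginal_likelihood=float(-res.fun),
        n_quadrature=n_quadrature,
        converged=True,
        boundary=bool(boundary),
    )


def bootstrap_percentile_ci(
    statistic,
    units,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    max_undefined_frac: float = 0.10,
    return_draws: bool = False,
):
    """Percentile CI from resampling units (hospitals) with replacement.

    ``statistic`` receives a resampled copy of ``units`` (DataFrame or
    array) and must return a float.  Resamples where it raises or returns a
    non-finite value are redrawn and counted; more than
    ``max_undefined_frac * reps`` such failures aborts.
    """
    n = len(units)
    if n < 2:
        raise InputError("need at least 2 units to bootstrap")
    rng = np.random.default_rng(seed)
    is_frame = isinstance(units, pd.DataFrame)
    draws = np.empty(reps)
    undefined = 0
    limit = int(np.ceil(max_undefined_frac * reps))
    i = 0
    while i < reps:
        idx = rng.integers(0, n, size=n)
        sample = units.iloc[idx] if is_frame else np.asarray(units)[idx]
        try:
            val = float(statistic(sample))
        except Exception:
            val = np.nan
        if not np.isfinite(val):
            undefined += 1
            if undefined > limit:
                raise FitError(
                    f"statistic undefined on more than {max_undefined_frac:.0%} "
                    f"of resamples ({undefined} failures)"
                )
            continue
        draws[i] = val
        i += 1
    if undefined:
        log.info("bootstrap redrew %d undefined resamples", undefined)
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if return_draws:
        return float(lo), float(hi), draws
    return float(lo), float(hi)


def variation_report(
    summaries: pd.DataFrame,
    quasi_sentinel: bool = False,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    zero_policy: str = "error",
    n_quadrature: int = 30,
) -> VariationReport:
    """RV ratios and the systematic-variation statistic with bootstrap CIs.

    RVs are computed on ``rate_adjusted`` (``rate_crude`` for a
    quasi-sentinel indicator); the variance statistic on ``(y_obs, e_exp)``.
    All three bootstraps resample hospitals (cluster bootstrap).
    """
    if len(summaries) < 5:
        raise InputError("need at least 5 hospitals")
    rate_col = "rate_crude" if quasi_sentinel else "rate_adjusted"
    for col in (rate_col, "y_obs", "e_exp"):
        if col not in summaries.columns:
            raise InputError(f"summaries lack '{col}'")

    def rv(hi, lo):
        return lambda df: ratio_of_variation(
            df[rate_col].to_numpy(), hi=hi, lo=lo, zero_policy=zero_policy
        )

    def eb(df):
        return fit_poisson_lognormal(
            df["y_obs"].to_numpy(), df["e_exp"].to_numpy(),
            n_quadrature=n_quadrature,
        ).sigma2

    out = {}
    for name, stat, sub in (
        ("rv_95_5", rv(95, 5), 1),
        ("rv_75_25", rv(75, 25), 2),
        ("eb", eb, 3),
    ):
        point = stat(summaries)
        lo, hi = bootstrap_percentile_ci(
            stat, summaries, reps=reps, alpha=alpha, seed=seed + sub
        )
        out[name] = EstimateCI(
            point=point, lo=min(lo, point), hi=max(hi, point)
        )
    return VariationReport(
        rv_95_5=out["rv_95_5"],
        rv_75_25=out["rv_75_25"],
        eb=out["eb"],
        n_hospitals=len(summaries),
        bootstrap_reps=reps,
        seed=seed,
    )


def mean_centred_log_incidence(
    summaries: pd.DataFrame, quasi_sentinel: bool = False
) -> pd.DataFrame:
    """Per-hospital mean-centred log adjusted incidence (plot data).

    Hospitals with a zero rate carry no log value and are dropped with a log
    message.
    """
    rate_col = "rate_crude" if quasi_sentinel else "rate_adjusted"
    df = summaries[["hospital_id", rate_col]].copy()
    zero = df[rate_col] <= 0
    if zero.any():
        log.info("dropping %d zero-rate hospitals from plot data", int(zero.sum()))
        df = df.loc[~zero]
    logs = np.log(df[rate_col].to_numpy())
    return pd.DataFrame(
        {
            "hospital_id": df["hospital_id"].to_numpy(),
            "centred_log_incidence": logs - logs.mean(),
        }
    )
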