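"""Patient-level logistic risk adjustment and indirectly standardised rates.

The logistic fit is a plain Newton/IRLS maximum-likelihood fit with the
convergence rule fixed by contract (relative log-likelihood change < 1e-8,
at most 100 iterations).  Age is centred at the cohort mean internally for
conditioning; reported coefficients are on the uncentred per-year scale.
Sex is coded female=1 / male=0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

from .cohort import Cohort
from .errors import FitError, InputError

__all__ = [
    "LogisticFit",
    "build_design",
    "fit_logistic",
    "screen_comorbidities",
    "c_statistic",
    "hospital_summaries",
    "adjusted_incidence",
    "coefficient_table",
]

log = logging.getLogger(__name__)

SEPARATION_BOUND = 15.0  # |log-odds| beyond this is treated as divergence


@dataclass
class LogisticFit:
    coefficients: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_obs: int
    n_iter: int
    separated: bool = False
    dropped: tuple = ()

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance.to_numpy())),
            index=self.coefficients.index,
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.coefficients.to_numpy())


def _encode_sex(values) -> np.ndarray:
    s = pd.Series(values)
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return (s.astype(str).str.lower() == "female").to_numpy(dtype=float)
    return s.to_numpy(dtype=float)


def build_design(
    records: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with leading intercept; 'sex' becomes female=1."""
    cols = [np.ones(len(records))]
    names = ["intercept"]
    for name in covariates:
        if name not in records.columns:
            raise InputError(f"covariate '{name}' missing from records")
        x = _encode_sex(records[name]) if name == "sex" else records[
            name
        ].to_numpy(dtype=float)
        cols.append(x)
        names.append(name)
    return np.column_stack(cols), names


def _irls(X, y, tol=1e-8, max_iter=100):
    n, p = X.shape
    beta = np.zeros(p)
    pbar = y.mean()
    beta[0] = np.log(pbar / (1 - pbar))
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FitError("singular information matrix") from exc
        beta = beta + step
        eta = X @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if converged:
            ll_old = ll
            break  # polish pass done; score now at machine precision
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True  # take one more Newton step before stopping
        ll_old = ll
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, cov, ll_old, converged, it


def fit_logistic(
    cohort: Cohort | pd.DataFrame,
    covariates: list[str],
    outcome: str = "event",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of the event on the covariates.

    Constant covariates are dropped with a warning; coefficient divergence
    beyond :data:`SEPARATION_BOUND` marks the fit as separated and
    non-converged rather than silently truncating.
    """
    records = cohort.records if isinstance(cohort, Cohort) else cohort
    y = records[outcome].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise FitError("need at least one event and one non-event")

    X, names = build_design(records, covariates)
    dropped = []
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            dropped.append(names[j])
            warnings.warn(
                f"dropping constant covariate '{names[j]}'", UserWarning,
                stacklevel=2,
            )
        else:
            keep.append(j)
    X = X[:, keep]
    names = [names[j] for j in keep]

    # centre age for conditioning; undo below so reports stay per-year
    age_mean = 0.0
    if "age" in names:
        ai = names.index("age")
        age_mean = float(X[:, ai].mean())
        X = X.copy()
        X[:, ai] -= age_mean

    beta_c, cov_c, ll, converged, n_iter = _irls(X, y, tol=tol, max_iter=max_iter)

    # transform centred parameters back: b0 = c0 - b_age * mean(age)
    T = np.eye(len(names))
    if "age" in names and age_mean != 0.0:
        T[0, names.index("age")] = -age_mean
    beta = T @ beta_c
    cov = T @ cov_c @ T.T

    separated = bool(np.any(np.abs(beta[1:]) > SEPARATION_BOUND)) if len(
        beta
    ) > 1 else False
    if separated:
        worst = names[1 + int(np.argmax(np.abs(beta[1:])))]
        log.warning("possible perfect separation on '%s'", worst)
        converged = False

    return LogisticFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        log_likelihood=ll,
        converged=converged,
        n_obs=len(y),
        n_iter=n_iter,
        separated=separated,
        dropped=tuple(dropped),
    )


def select_by_or(odds_ratios: pd.Series, threshold: float = 2.0) -> list[str]:
    """Inclusive rule: keep a candidate iff its adjusted OR >= threshold."""
    return [name for name, v in odds_ratios.items() if v >= threshold]


def screen_comorbidities(
    cohort: Cohort,
    candidates: list[str],
    or_threshold: float = 2.0,
) -> list[str]:
    """Select comorbidities whose jointly adjusted OR meets the threshold.

    A single patient-level model with age, sex and all candidates is fitted;
    candidates with adjusted OR >= ``or_threshold`` (inclusive) are kept.
    Age and sex are always retained by the caller and are not screened here.
    """
    if not candidates:
        raise InputError("no candidate comorbidities supplied")
    fit = fit_logistic(cohort, ["age", "sex"] + list(candidates))
    if not fit.converged:
        raise FitError("screening model did not converge")
    present = [c for c in candidates if c in fit.coefficients.index]
    ors = np.exp(fit.coefficients.loc[present])
    selected = select_by_or(ors, or_threshold)
    log.info(
        "screened %d/%d candidates at OR >= %g: %s",
        len(selected), len(candidates), or_threshold, selected,
    )
    return selected


def crude_rate_per_1000(events, at_risk):
    """Crude incidence per 1,000 at-risk discharges (scalar or vector)."""
    if np.any(np.asarray(at_risk) <= 0):
        raise InputError("at_risk must be positive")
    return 1000.0 * events / at_risk


def c_statistic(scores: np.ndarray, events: np.ndarray) -> float:
    """Concordance: P(score_event > score_non-event), ties counted 1/2.

    Computed exactly via midranks (Mann–Whitney), so it is invariant under
    strictly monotone transforms of the score.
    """
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events).astype(bool)
    n1 = int(events.sum())
    n0 = int((~events).sum())
    if n1 == 0 or n0 == 0:
        raise FitError("c statistic undefined without both events and non-events")
    ranks = rankdata(scores)
    u = ranks[events].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def c_statistic_from_fit(fit: LogisticFit, cohort: Cohort,
                         covariates: list[str]) -> float:
    if not fit.converged:
        raise FitError("fit did not converge")
    X, _ = build_design(cohort.records, covariates)
    keep = [i for i, n in enumerate(["intercept"] + list(covariates))
            if n in fit.coefficients.index]
    return c_statistic(fit.predict(X[:, keep]), cohort.records["event"].to_numpy())


def hospital_summaries(
    fit: LogisticFit, cohort: Cohort, covariates: list[str]
) -> pd.DataFrame:
    """Observed and expected events per hospital from a converged fit.

    ``e_exp`` is the sum of fitted probabilities over the hospital's
    records; with an intercept in the model the totals identity
    ``sum(e_exp) == sum(y_obs)`` holds by the IRLS score equation.
    """
    if not fit.converged:
        raise FitError("fit did not converge")
    if fit.n_obs != len(cohort.records):
        raise InputError("fit was not estimated on this cohort")
    X, names = build_design(cohort.records, covariates)
    keep = [i for i, n in enumerate(names) if n in fit.coefficients.index]
    p = fit.predict(X[:, keep])
    df = pd.DataFrame(
        {
            "hospital_id": cohort.records["hospital_id"].to_numpy(),
            "event": cohort.records["event"].to_numpy(dtype=float),
            "p": p,
        }
    )
    g = df.groupby("hospital_id")
    out = pd.DataFrame(
        {
            "y_obs": g["event"].sum().astype(int),
            "e_exp": g["p"].sum(),
            "n": g.size(),
        }
    ).reset_index()
    out["rate_crude"] = crude_rate_per_1000(out["y_obs"], out["n"])
    return out


def adjusted_incidence(
    summaries: pd.DataFrame, quasi_sentinel: bool = False
) -> pd.DataFrame:
    """Indirect standardisation: rate = 1000 * (O/E) * pooled rate.

    For a quasi-sentinel indicator the crude rate is used unchanged.
    """
    out = summaries.copy()
    if quasi_sentinel:
        out["rate_adjusted"] = out["rate_crude"]
        return out
    zero = out.loc[out["e_exp"] <= 0, "hospital_id"].tolist()
    if zero:
        raise FitError(f"expected count is zero for hospitals: {zero}")
    pooled = out["y_obs"].sum() / out["n"].sum()
    out["rate_adjusted"] = 1000.0 * (out["y_obs"] / out["e_exp"]) * pooled
    return out


def coefficient_table(fit: LogisticFit, alpha: float = 0.05) -> pd.DataFrame:
    """OR / CI95 / SE table for reporting."""
    z = norm.ppf(1 - alpha / 2)
    se = fit.se
    return pd.DataFrame(
        {
            "coef": fit.coefficients,
            "se": se,
            "or": np.exp(fit.coefficients),
            "or_lo": np.exp(fit.coefficients - z * se),
            "or_hi": np.exp(fit.coefficients + z * se),
        }
    )
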