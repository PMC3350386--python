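"""Hospital profiling from shrunken residuals of the multilevel fit.

The shrunken residual for hospital *j* is the mode of the conditional
posterior of its random intercept given the data and the fitted parameters;
its comparative standard error comes from the curvature at that mode.  A
hospital is flagged "above" when the residual's confidence interval sits
entirely above 0 (the population-average prediction), "below" when entirely
below.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort
from .errors import FitError, InputError
from .glmm import GlmmFit

__all__ = [
    "FlagReport",
    "shrunken_residuals",
    "flag_hospitals",
    "caterpillar_data",
    "compare_model_variants",
    "plot_caterpillar",
]


@dataclass(frozen=True)
class FlagReport:
    psi_name: str
    n_hospitals: int
    n_above: int
    n_below: int
    fraction_above: float
    alpha: float

    def to_dict(self) -> dict:
        return {
            "psi": self.psi_name,
            "n_hospitals": self.n_hospitals,
            "n_above": self.n_above,
            "n_below": self.n_below,
            "fraction_above": self.fraction_above,
            "alpha": self.alpha,
        }


def shrunken_residuals(fit: GlmmFit, cohort: Cohort | None = None) -> pd.DataFrame:
    """Posterior-mode hospital effects with comparative standard errors.

    Returns one row per hospital: ``hospital_id, u_hat, se_comp, rank,
    flag`` (flag filled by :func:`flag_hospitals`).  Rank is ascending in
    ``u_hat``.
    """
    if not fit.converged:
        raise FitError("fit did not converge")
    if cohort is not None:
        counts = cohort.records.groupby("hospital_id").size()
        missing = [h for h in fit.hospital_ids if counts.get(h, 0) == 0]
        if missing or set(counts.index) != set(fit.hospital_ids):
            raise InputError(
                f"cohort/fit hospital mismatch (no records for {missing})"
            )
    se = fit.b_sd
    if np.any(se <= 0):
        raise FitError("non-positive comparative standard error")
    out = pd.DataFrame(
        {
            "hospital_id": fit.hospital_ids.to_numpy(),
            "u_hat": fit.b_hat,
            "se_comp": se,
        }
    )
    out["rank"] = out["u_hat"].rank(method="first").astype(int)
    out["flag"] = "none"
    return out


def flag_hospitals(
    estimates: pd.DataFrame, alpha: float = 0.05, psi_name: str = ""
) -> tuple[FlagReport, pd.DataFrame]:
    """Flag hospitals whose residual interval excludes 0.

    above: ``u_hat - z * se_comp > 0``; below: ``u_hat + z * se_comp < 0``.
    """
    for col in ("u_hat", "se_comp"):
        if col not in estimates.columns:
            raise InputError(f"estimates lack '{col}'")
    z = norm.ppf(1 - alpha / 2)
    out = estimates.copy()
    lo = out["u_hat"] - z * out["se_comp"]
    hi = out["u_hat"] + z * out["se_comp"]
    out["flag"] = np.select([lo > 0, hi < 0], ["above", "below"], default="none")
    n_above = int((out["flag"] == "above").sum())
    n_below = int((out["flag"] == "below").sum())
    report = FlagReport(
        psi_name=psi_name,
        n_hospitals=len(out),
        n_above=n_above,
        n_below=n_below,
        fraction_above=n_above / len(out) if len(out) else 0.0,
        alpha=alpha,
    )
    return report, out


def caterpillar_data(estimates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Plot table sorted ascending by u_hat (ties broken by hospital_id)."""
    z = norm.ppf(1 - alpha / 2)
    out = estimates.copy()
    out["lo"] = out["u_hat"] - z * out["se_comp"]
    out["hi"] = out["u_hat"] + z * out["se_comp"]
    out = out.sort_values(
        ["u_hat", "hospital_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["position"] = np.arange(1, len(out) + 1)
    cols = ["position", "hospital_id", "u_hat", "lo", "hi", "se_comp", "flag"]
    return out[[c for c in cols if c in out.columns]]


def compare_model_variants(
    estimates_a: pd.DataFrame, estimates_b: pd.DataFrame
) -> dict:
    """Pearson correlation of residuals plus flag-change bookkeeping.

    Both inputs must cover the same hospital set (typically the original
    model vs a recalibrated or subset variant).
    """
    a = estimates_a.set_index("hospital_id")
    b = estimates_b.set_index("hospital_id")
    if set(a.index) != set(b.index):
        raise InputError("hospital sets differ between variants")
    b = b.reindex(a.index)
    ua, ub = a["u_hat"].to_numpy(), b["u_hat"].to_numpy()
    if np.std(ua) == 0 or np.std(ub) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(ua, ub)[0, 1])
    fa = a.get("flag", pd.Series("none", index=a.index)).astype(str)
    fb = b.get("flag", pd.Series("none", index=b.index)).astype(str)
    changed = fa != fb
    return {
        "pearson_r": r,
        "n_hospitals": len(a),
        "n_flag_changes": int(changed.sum()),
        "changed_hospitals": sorted(a.index[changed].tolist()),
    }


def plot_caterpillar(estimates: pd.DataFrame, alpha: float = 0.05, ax=None):
    """Render a caterpillar plot (optional; needs matplotlib)."""
    import matplotlib.pyplot as plt

    data = caterpillar_data(estimates, alpha=alpha)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    x = data["position"]
    ax.errorbar(
        x, data["u_hat"],
        yerr=[data["u_hat"] - data["lo"], data["hi"] - data["u_hat"]],
        fmt="o", ms=2, lw=0.5, capsize=0,
    )
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("hospitals sorted by random effect")
    ax.set_ylabel("hospital effect (log-odds)")
    return ax
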