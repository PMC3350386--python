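"""Synthetic hospital-discharge data with recorded ground truth.

Generates the two views the downstream analyses consume:

* a discharge-level table (one row per admission, with age, sex, binary
  comorbidity flags, a secondary-diagnosis count and per-indicator
  eligibility/event flags), where the event probability for a patient in
  hospital *j* is ``inv_logit(beta . x + u_j)`` with hospital effects
  ``u_j ~ N(0, sigma2_hospital)``; and
* a hospital-level count table ``(y_j, e_j)`` where ``y_j ~ Poisson(e_j r_j)``
  and ``log r_j ~ N(mu, sigma2)``.

Comorbidity flags are generated independently of each other; real
comorbidities co-occur, but no joint law is assumed here and none is needed
by the estimators under test.  All generators are pure functions of
``(config, seed)``: a single global seed is split into named sub-streams
("hospitals", "discharges") via :class:`numpy.random.SeedSequence`, so each
stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "generate_hospitals",
    "generate_discharges",
    "generate_hospital_counts",
]

_STREAMS = ("hospitals", "discharges")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the discharge-level data generating process.

    ``beta`` holds log-odds coefficients and must contain ``intercept``,
    ``age`` (per year) and ``sex`` (female=1); any further key must name a
    comorbidity listed in ``comorbidity_prevalences``.
    """

    n_hospitals: int
    beta: Mapping[str, float]
    comorbidity_prevalences: Mapping[str, float] = field(default_factory=dict)
    hospital_size_mean: float = 800.0
    hospital_size_dispersion: float = 1.2
    sigma2_hospital: float = 0.0
    age_mean: float = 65.0
    age_sd: float = 18.0
    age_min: float = 18.0
    age_max: float = 100.0
    prop_female: float = 0.5
    beds_mean: float = 300.0
    beds_dispersion: float = 1.5
    teaching_min_beds: int = 500
    coding_intensity_effect: float = 0.0
    secondary_dx_rate: float = 3.5
    psi_name: str = "psi"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals <= 0:
            raise ConfigurationError("n_hospitals must be positive")
        if self.sigma2_hospital < 0:
            raise ConfigurationError("sigma2_hospital must be >= 0")
        for k in ("intercept", "age", "sex"):
            if k not in self.beta:
                raise ConfigurationError(f"beta must define '{k}'")
        for name, p in self.comorbidity_prevalences.items():
            if not 0.0 < p < 1.0:
                raise ConfigurationError(
                    f"prevalence for '{name}' must lie in (0, 1), got {p}"
                )
        if not 0.0 < self.prop_female < 1.0:
            raise ConfigurationError("prop_female must lie in (0, 1)")
        if self.age_min >= self.age_max:
            raise ConfigurationError("age_min must be < age_max")
        if self.coding_intensity_effect < 0:
            raise ConfigurationError("coding_intensity_effect must be >= 0")

    @property
    def comorbidity_names(self) -> list[str]:
        return list(self.comorbidity_prevalences)

    def rng(self, stream: str) -> np.random.Generator:
        """Named, order-independent sub-stream of the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta"] = dict(self.beta)
        d["comorbidity_prevalences"] = dict(self.comorbidity_prevalences)
        return d


def _negative_binomial(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    # dispersion is the NB shape k; variance = mean + mean^2/k
    if dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_hospitals(config: GeneratorConfig) -> pd.DataFrame:
    """Draw hospital profiles: sizes, beds, teaching status and true effects.

    Returns a frame with columns ``hospital_id, n_eligible, beds, teaching,
    u_true``.  ``u_true ~ N(0, sigma2_hospital)`` i.i.d.; eligible-volume and
    bed counts follow negative-binomial laws so the skew between small and
    very large providers is representable.  Deterministic for a fixed seed.
    """
    rng = config.rng("hospitals")
    J = config.n_hospitals
    width = len(str(J))
    ids = [f"H{i + 1:0{width}d}" for i in range(J)]
    n_eligible = np.maximum(
        1, _negative_binomial(rng, config.hospital_size_mean,
                              config.hospital_size_dispersion, J)
    )
    beds = np.maximum(
        10, _negative_binomial(rng, config.beds_mean, config.beds_dispersion, J)
    )
    if config.sigma2_hospital > 0:
        u = rng.normal(0.0, np.sqrt(config.sigma2_hospital), size=J)
    else:
        u = np.zeros(J)
        rng.normal(size=J)  # keep stream alignment across sigma2 settings
    return pd.DataFrame(
        {
            "hospital_id": ids,
            "n_eligible": n_eligible.astype(int),
            "beds": beds.astype(int),
            "teaching": beds >= config.teaching_min_beds,
            "u_true": u,
        }
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    from scipy.stats import truncnorm

    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_discharges(
    hospitals: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Simulate one discharge row per eligible admission.

    Event probability is ``inv_logit(beta . x + u_true)`` computed from the
    *true* comorbidity flags; when ``coding_intensity_effect > 0`` each
    hospital under-records true flags with its own probability (a recording
    artifact: risk is unchanged), and the recorded flags are what the output
    table carries.  ``n_secondary_dx`` counts recorded flags plus a Poisson
    number of unrelated secondary diagnoses scaled by the hospital's
    recording propensity.
    """
    if len(hospitals) == 0:
        raise ConfigurationError("hospitals table is empty")
    unknown = [
        k for k in config.beta
        if k not in ("intercept", "age", "sex")
        and k not in config.comorbidity_prevalences
    ]
    if unknown:
        raise ConfigurationError(
            f"beta names unknown comorbidities: {unknown!r}; "
            "add them to comorbidity_prevalences"
        )
    rng = config.rng("discharges")
    sizes = hospitals["n_eligible"].to_numpy()
    n = int(sizes.sum())
    hosp_idx = np.repeat(np.arange(len(hospitals)), sizes)

    age = _truncated_normal(
        rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n
    )
    female = rng.random(n) < config.prop_female

    eta = (
        config.beta["intercept"]
        + config.beta["age"] * age
        + config.beta["sex"] * female
        + hospitals["u_true"].to_numpy()[hosp_idx]
    )

    true_flags: dict[str, np.ndarray] = {}
    for name, prev in config.comorbidity_prevalences.items():
        flag = rng.random(n) < prev
        true_flags[name] = flag
        coef = config.beta.get(name, 0.0)
        if coef:
            eta = eta + coef * flag

    # per-hospital recording propensity on the logit scale; 1.0 when exact
    if config.coding_intensity_effect > 0:
        shift = rng.normal(0.0, config.coding_intensity_effect, len(hospitals))
        p_record = expit(2.2 + shift)  # mean recording ~0.90
    else:
        p_record = np.ones(len(hospitals))
    p_rec_row = p_record[hosp_idx]

    recorded: dict[str, np.ndarray] = {}
    for name, flag in true_flags.items():
        keep = rng.random(n) < p_rec_row
        recorded[name] = flag & keep

    n_flags = (
        np.sum([recorded[name] for name in true_flags], axis=0)
        if true_flags
        else np.zeros(n)
    )
    extra_rate = config.secondary_dx_rate * p_rec_row / max(p_record.mean(), 1e-12)
    n_secondary = n_flags.astype(int) + rng.poisson(extra_rate)

    event = rng.random(n) < expit(eta)

    out = pd.DataFrame(
        {
            "hospital_id": hospitals["hospital_id"].to_numpy()[hosp_idx],
            "age": age,
            "sex": np.where(female, "female", "male"),
        }
    )
    for name in config.comorbidity_prevalences:
        out[name] = recorded[name].astype(int)
    out["n_secondary_dx"] = n_secondary
    out[f"eligible_{config.psi_name}"] = 1
    out[f"event_{config.psi_name}"] = event.astype(int)
    return out


def generate_hospital_counts(
    n_units: int,
    mu: float,
    sigma2: float,
    expected,
    seed: int = 0,
) -> pd.DataFrame:
    """Hospital-level counts from the Poisson–lognormal two-step model.

    ``r_j = exp(N(mu, sigma2))`` and ``y_j ~ Poisson(e_j * r_j)``.  The frame
    carries ground truth in ``.attrs``.  ``expected`` may be a scalar or a
    length-``n_units`` vector of positive reals.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if n_units <= 0:
        raise ConfigurationError("n_units must be positive")
    e = np.broadcast_to(np.asarray(expected, dtype=float), (n_units,)).copy()
    if np.any(e <= 0):
        raise ValueError("expected counts must all be > 0")
    rng = np.random.default_rng(seed)
    log_r = rng.normal(mu, np.sqrt(sigma2), size=n_units) if sigma2 > 0 else np.full(
        n_units, float(mu)
    )
    y = rng.poisson(e * np.exp(log_r))
    df = pd.DataFrame(
        {
            "unit_id": [f"U{i + 1:04d}" for i in range(n_units)],
            "y": y.astype(int),
            "e": e,
        }
    )
    df.attrs["mu"] = float(mu)
    df.attrs["sigma2"] = float(sigma2)
    df.attrs["seed"] = int(seed)
    return df
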