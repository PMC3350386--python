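import numpy as np
import pandas as pd
import pytest

from psivar.cohort import Cohort, cohort_from_flags
from psivar.synthetic import (
    GeneratorConfig,
    generate_discharges,
    generate_hospitals,
)


def make_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_hospitals=20,
        beta={"intercept": -4.0, "age": 0.01, "sex": 0.1},
        comorbidity_prevalences={},
        hospital_size_mean=300.0,
        hospital_size_dispersion=4.0,
        sigma2_hospital=0.2,
        seed=123,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture
def small_config() -> GeneratorConfig:
    return make_config()


@pytest.fixture
def small_cohort(small_config) -> Cohort:
    hospitals = generate_hospitals(small_config)
    discharges = generate_discharges(hospitals, small_config)
    return cohort_from_flags(discharges, "psi", hospital_attrs=hospitals)


def cohort_from_records(records: pd.DataFrame, **kwargs) -> Cohort:
    """Hand-built cohort for toy fixtures (records must carry 'event')."""
    g = records.groupby("hospital_id")
    hospitals = pd.DataFrame(
        {"n_eligible": g.size(), "n_events": g["event"].sum().astype(int)}
    )
    return Cohort(
        psi_name=kwargs.pop("psi_name", "toy"),
        records=records.reset_index(drop=True),
        hospitals=hospitals,
        **kwargs,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
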