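"""Per-indicator analysis cohorts from raw discharge records.

Code matching is generic and list-driven: indicator definitions and the
comorbidity map are plain code-prefix sets supplied by the user (no clinical
lists ship with the package).  Codes are normalised by stripping dots and
upper-casing before prefix comparison.  Each discharge is treated as an
independent record; no patient-level de-duplication is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import CohortError, EmptyCohortError, InputError

__all__ = [
    "PsiDefinition",
    "ComorbidityMap",
    "Cohort",
    "map_comorbidities",
    "build_cohort",
    "cohort_from_flags",
    "apply_hospital_filter",
    "coding_intensity_covariate",
    "subset_largest",
]

log = logging.getLogger(__name__)

CODES_COLUMN = "secondary_dx_codes"


def normalize_code(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


def _split_codes(value) -> list[str]:
    """Codes may arrive as list/tuple or as a ';'-delimited string."""
    if isinstance(value, (list, tuple, np.ndarray)):
        return [normalize_code(c) for c in value if str(c).strip()]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    return [normalize_code(c) for c in str(value).split(";") if c.strip()]


def _matches_any(codes: list[str], prefixes: frozenset[str]) -> bool:
    return any(c.startswith(p) for c in codes for p in prefixes)


@dataclass(frozen=True)
class PsiDefinition:
    """One safety indicator: numerator/denominator code-prefix rules."""

    name: str
    numerator_codes: frozenset[str] = frozenset()
    denominator_inclusion_codes: frozenset[str] = frozenset()
    denominator_exclusion_codes: frozenset[str] = frozenset()
    is_quasi_sentinel: bool = False

    def __post_init__(self):
        for attr in ("numerator_codes", "denominator_inclusion_codes",
                     "denominator_exclusion_codes"):
            object.__setattr__(
                self, attr,
                frozenset(normalize_code(c) for c in getattr(self, attr)),
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PsiDefinition":
        return cls(
            name=d["name"],
            numerator_codes=frozenset(d.get("numerator_codes", ())),
            denominator_inclusion_codes=frozenset(
                d.get("denominator_inclusion_codes", ())
            ),
            denominator_exclusion_codes=frozenset(
                d.get("denominator_exclusion_codes", ())
            ),
            is_quasi_sentinel=bool(d.get("is_quasi_sentinel", False)),
        )


@dataclass(frozen=True)
class ComorbidityMap:
    """Comorbidity name -> set of diagnosis-code prefixes."""

    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self):
        clean = {}
        for name, prefixes in self.mapping.items():
            pfx = frozenset(normalize_code(p) for p in prefixes)
            if not pfx or any(not p for p in pfx):
                raise InputError(f"empty prefix for comorbidity '{name}'")
            clean[name] = pfx
        object.__setattr__(self, "mapping", clean)

    @property
    def names(self) -> list[str]:
        return list(self.mapping)

    @classmethod
    def from_yaml(cls, path) -> "ComorbidityMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


@dataclass
class Cohort:
    """Eligible records for one indicator plus per-hospital bookkeeping.

    ``records`` holds eligible rows only, with an ``event`` column;
    ``hospitals`` is indexed by hospital_id with ``n_eligible``/``n_events``
    and, when available, ``beds``/``teaching`` attributes.
    ``exclusions`` logs (hospital_id, n_eligible, reason) rows dropped by
    filters.
    """

    psi_name: str
    records: pd.DataFrame
    hospitals: pd.DataFrame
    is_quasi_sentinel: bool = False
    exclusions: list = field(default_factory=list)

    @property
    def denominator(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return int(self.records["event"].sum())

    @property
    def n_hospitals(self) -> int:
        return len(self.hospitals)

    def validate(self) -> None:
        counts = self.records.groupby("hospital_id").size()
        if not counts.sum() == self.denominator:
            raise CohortError("per-hospital counts do not sum to denominator")


def _hospital_table(records: pd.DataFrame,
                    attrs: pd.DataFrame | None = None) -> pd.DataFrame:
    g = records.groupby("hospital_id")
    tab = pd.DataFrame(
        {"n_eligible": g.size(), "n_events": g["event"].sum().astype(int)}
    )
    if attrs is not None:
        cols = [c for c in ("beds", "teaching") if c in attrs.columns]
        if cols:
            tab = tab.join(attrs.set_index("hospital_id")[cols], how="left")
    return tab.sort_index()


def map_comorbidities(
    records: pd.DataFrame,
    cmap: ComorbidityMap,
    codes_column: str = CODES_COLUMN,
) -> pd.DataFrame:
    """Set one binary flag per comorbidity from secondary-diagnosis codes.

    A flag is 1 iff any secondary code starts with one of its mapped
    prefixes.  Idempotent: re-running overwrites the same columns.
    """
    if codes_column not in records.columns:
        raise InputError(f"records lack a '{codes_column}' column")
    out = records.copy()
    code_lists = records[codes_column].map(_split_codes)
    for name, prefixes in cmap.mapping.items():
        out[name] = code_lists.map(lambda cs: int(_matches_any(cs, prefixes)))
    return out


def build_cohort(
    records: pd.DataFrame,
    psi: PsiDefinition,
    codes_column: str = CODES_COLUMN,
    hospital_attrs: pd.DataFrame | None = None,
) -> Cohort:
    """Apply denominator inclusion/exclusion and numerator rules.

    eligible = matches any inclusion prefix and no exclusion prefix;
    event = eligible and matches any numerator prefix.  Exclusion takes
    precedence over the numerator.
    """
    if not psi.denominator_inclusion_codes:
        raise CohortError(f"PSI '{psi.name}': empty denominator definition")
    if codes_column not in records.columns:
        raise InputError(f"records lack a '{codes_column}' column")
    code_lists = records[codes_column].map(_split_codes)
    incl = code_lists.map(
        lambda cs: _matches_any(cs, psi.denominator_inclusion_codes)
    )
    excl = code_lists.map(
        lambda cs: _matches_any(cs, psi.denominator_exclusion_codes)
    )
    eligible = incl & ~excl
    num = code_lists.map(lambda cs: _matches_any(cs, psi.numerator_codes))
    out = records.loc[eligible].copy()
    out["event"] = (num[eligible]).astype(int)
    if out.empty:
        raise EmptyCohortError(f"PSI '{psi.name}': no eligible records")
    return Cohort(
        psi_name=psi.name,
        records=out.reset_index(drop=True),
        hospitals=_hospital_table(out, hospital_attrs),
        is_quasi_sentinel=psi.is_quasi_sentinel,
    )


def cohort_from_flags(
    records: pd.DataFrame,
    psi_name: str,
    hospital_attrs: pd.DataFrame | None = None,
    is_quasi_sentinel: bool = False,
) -> Cohort:
    """Build a cohort from pre-computed ``eligible_<psi>``/``event_<psi>`` flags."""
    ecol, vcol = f"eligible_{psi_name}", f"event_{psi_name}"
    for col in (ecol, vcol):
        if col not in records.columns:
            raise InputError(f"records lack a '{col}' column")
    bad = records[vcol].astype(bool) & ~records[ecol].astype(bool)
    if bad.any():
        raise CohortError(f"{int(bad.sum())} records have event without eligibility")
    out = records.loc[records[ecol].astype(bool)].copy()
    if out.empty:
        raise EmptyCohortError(f"PSI '{psi_name}': no eligible records")
    out["event"] = out[vcol].astype(int)
    out = out.drop(columns=[ecol, vcol]).reset_index(drop=True)
    return Cohort(
        psi_name=psi_name,
        records=out,
        hospitals=_hospital_table(out, hospital_attrs),
        is_quasi_sentinel=is_quasi_sentinel,
    )


def apply_hospital_filter(cohort: Cohort, min_cases: int = 30) -> Cohort:
    """Drop hospitals with fewer than ``min_cases`` eligible records.

    Idempotent; every removal is logged and recorded in ``exclusions``.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    counts = cohort.hospitals["n_eligible"]
    drop = counts.index[counts < min_cases]
    if len(drop) == len(counts):
        raise EmptyCohortError(
            f"PSI '{cohort.psi_name}': all hospitals below {min_cases} eligible cases"
        )
    exclusions = list(cohort.exclusions)
    for hid in drop:
        n = int(counts.loc[hid])
        log.info("excluding hospital %s (%d eligible < %d)", hid, n, min_cases)
        exclusions.append((hid, n, f"fewer than {min_cases} eligible cases"))
    keep = ~cohort.records["hospital_id"].isin(set(drop))
    records = cohort.records.loc[keep].reset_index(drop=True)
    return replace(
        cohort,
        records=records,
        hospitals=cohort.hospitals.drop(index=drop),
        exclusions=exclusions,
    )


def coding_intensity_covariate(
    cohort: Cohort, threshold: int | str = "median"
) -> tuple[Cohort, int]:
    """Add a binary high-coding-intensity covariate to the records.

    ``high_coding = 1`` iff ``n_secondary_dx >= threshold``; with
    ``threshold="median"`` the cohort median is used and returned.
    """
    if "n_secondary_dx" not in cohort.records.columns:
        raise InputError("records lack 'n_secondary_dx'")
    if threshold == "median":
        thr = int(np.floor(cohort.records["n_secondary_dx"].median()))
        log.info("coding-intensity threshold set to cohort median = %d", thr)
    else:
        thr = int(threshold)
    records = cohort.records.copy()
    records["high_coding"] = (records["n_secondary_dx"] >= thr).astype(int)
    return replace(cohort, records=records), thr


def subset_largest(
    cohort: Cohort, min_beds: int = 450, teaching_only: bool = True
) -> Cohort:
    """Restrict to teaching hospitals with strictly more than ``min_beds`` beds."""
    for col in ("beds",) + (("teaching",) if teaching_only else ()):
        if col not in cohort.hospitals.columns:
            raise InputError(f"hospital attributes lack '{col}'")
    mask = cohort.hospitals["beds"] > min_beds
    if teaching_only:
        mask &= cohort.hospitals["teaching"].astype(bool)
    keep_ids = set(cohort.hospitals.index[mask])
    if not keep_ids:
        raise EmptyCohortError("no hospital satisfies the largest-hospitals subset")
    records = cohort.records.loc[
        cohort.records["hospital_id"].isin(keep_ids)
    ].reset_index(drop=True)
    exclusions = list(cohort.exclusions) + [
        (hid, int(cohort.hospitals.loc[hid, "n_eligible"]),
         f"not a teaching hospital with more than {min_beds} beds")
        for hid in cohort.hospitals.index[~mask]
    ]
    return replace(
        cohort,
        records=records,
        hospitals=cohort.hospitals.loc[mask],
        exclusions=exclusions,
    )
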