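"""From raw claims to analysis-ready survival rows.

A cancer case needs both a qualifying diagnosis code (prefix C18/C19/C20 by
default) and at least one treatment-evidence record (colonoscopy, operation,
chemotherapy or radiotherapy); the date of the first qualifying treatment is
time zero (study entry).  Cases entering during the initial washout window
of the data coverage are excluded so that only newly diagnosed patients
remain.  Follow-up runs from time zero to death or the administrative end
of follow-up, whichever comes first; deaths from causes other than the
target cancer are censoring events for the cancer-specific outcome.

The treatment-category covariate is the staging proxy: the combination of
treatment kinds received from time zero onwards, collapsed into the six
categories (colonoscopy only marks patients who received no actual cancer
treatment; chemo/radiotherapy without operation marks advanced disease).

The Charlson comorbidity category is consumed as a precomputed 3-level
input per patient (the simulator emits it directly; real-data users must
supply it), because deriving it from raw diagnosis histories requires a
mapping version and lookback that are deployment-specific.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .claims_model import (
    AGE_BANDS,
    CCI_CATEGORIES,
    COHORT_COLUMNS,
    TREATMENT_KINDS,
    ClaimsBundle,
    CohortRow,
    ValidationError,
)

__all__ = [
    "CaseDefinition",
    "WashoutPolicy",
    "identify_cases",
    "apply_washout",
    "derive_treatment_category",
    "age_band",
    "build_survival_row",
    "build_cohort",
    "write_cohort",
    "read_cohort",
]

DEFAULT_END_OF_FOLLOWUP = dt.date(2015, 12, 31)


@dataclass(frozen=True)
class CaseDefinition:
    """Conjunctive case definition: diagnosis prefix AND treatment evidence."""

    diagnosis_prefixes: frozenset[str] = frozenset({"C18", "C19", "C20"})
    evidence_kinds: frozenset[str] = frozenset(TREATMENT_KINDS)

    def __post_init__(self):
        if not self.diagnosis_prefixes or not self.evidence_kinds:
            raise ValidationError("case definition sets must be non-empty")
        bad = self.evidence_kinds - set(TREATMENT_KINDS)
        if bad:
            raise ValidationError(f"unknown evidence kinds: {sorted(bad)}")


@dataclass(frozen=True)
class WashoutPolicy:
    """Exclude cases entering within ``washout_years`` of ``data_start``.

    The washout keys on first treatment date (= study entry): a case is
    removed iff its entry falls in ``[data_start, data_start + washout_years)``
    measured in calendar years.
    """

    washout_years: int = 2
    data_start: dt.date = dt.date(2002, 1, 1)

    def __post_init__(self):
        if self.washout_years < 0:
            raise ValidationError("washout_years must be >= 0")

    @property
    def washout_end(self) -> dt.date:
        try:
            return self.data_start.replace(
                year=self.data_start.year + self.washout_years
            )
        except ValueError:  # Feb 29 anchor
            return self.data_start.replace(
                year=self.data_start.year + self.washout_years, day=28
            )


def identify_cases(bundle: ClaimsBundle, case_def: CaseDefinition = CaseDefinition()
                   ) -> pd.DataFrame:
    """Find treatment-evidenced cancer cases and their entry dates.

    Returns a DataFrame (patient_id, first_treatment_date) sorted by
    patient_id; a patient qualifies iff they have >= 1 diagnosis whose code
    starts with a qualifying prefix and >= 1 treatment record of a
    qualifying kind.  Time zero is the earliest qualifying treatment date.
    """
    dx = bundle.diagnoses
    prefixes = tuple(case_def.diagnosis_prefixes)
    if len(dx):
        diagnosed = set(dx.loc[dx["code"].str.upper().str.startswith(prefixes),
                               "patient_id"])
    else:
        diagnosed = set()
    tx = bundle.treatments
    if len(tx):
        tx = tx.loc[tx["kind"].isin(case_def.evidence_kinds)]
    if len(tx) == 0 or not diagnosed:
        return pd.DataFrame(columns=["patient_id", "first_treatment_date"])
    tx = tx.loc[tx["patient_id"].isin(diagnosed)]
    first = (
        tx.assign(date=pd.to_datetime(tx["date"]))
        .groupby("patient_id", sort=True)["date"]
        .min()
        .dt.date
    )
    return (
        first.rename("first_treatment_date")
        .reset_index()
        .sort_values("patient_id")
        .reset_index(drop=True)
    )


def apply_washout(cases: pd.DataFrame, policy: WashoutPolicy) -> pd.DataFrame:
    """Drop cases whose entry date falls inside the washout window."""
    if len(cases) == 0 or policy.washout_years == 0:
        return cases.reset_index(drop=True)
    end = policy.washout_end
    keep = ~cases["first_treatment_date"].map(
        lambda d: policy.data_start <= d < end
    )
    return cases.loc[keep].reset_index(drop=True)


def derive_treatment_category(
    bundle: ClaimsBundle,
    patient_id: str,
    t0: dt.date,
    attribution_end: dt.date | None = None,
) -> str:
    """Collapse the set of treatment kinds from t0 onwards into one of the
    six staging-proxy categories.

    The attribution window defaults to everything on or after ``t0``.
    """
    tx = bundle.treatments
    mask = tx["patient_id"] == patient_id
    dates = pd.to_datetime(tx.loc[mask, "date"]).dt.date
    in_window = dates >= t0
    if attribution_end is not None:
        in_window &= dates <= attribution_end
    kinds = set(tx.loc[mask].loc[in_window.to_numpy(), "kind"])
    return category_from_kinds(kinds)


def category_from_kinds(kinds: set[str]) -> str:
    """Map a set of received treatment kinds to its category label.

    The six categories are exhaustive and mutually exclusive: operation
    combined with adjuvant therapy dominates, chemo/radio without operation
    marks palliative treatment, colonoscopy alone marks untreated patients.
    """
    if not kinds:
        raise ValidationError("patient has no treatment records in the window")
    has_op = "operation" in kinds
    has_chemo = "chemotherapy" in kinds
    has_radio = "radiotherapy" in kinds
    if has_op:
        if has_chemo and has_radio:
            return "operation_both"
        if has_chemo:
            return "operation_chemo"
        if has_radio:
            return "operation_radio"
        return "operation_only"
    if has_chemo or has_radio:
        return "chemo_or_radio_without_operation"
    return "colonoscopy_only"


def age_band(birth_year: int, t0: dt.date) -> str:
    """Table-style age band from calendar-year age at study entry."""
    age = t0.year - birth_year
    if age < 15:
        raise ValidationError(f"age {age} at entry below the 15-year minimum")
    for band, (lo, hi) in zip(
        AGE_BANDS, [(15, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 200)]
    ):
        if lo <= age <= hi:
            return band
    raise ValidationError(f"age {age} outside all bands")  # pragma: no cover


def build_survival_row(
    bundle: ClaimsBundle,
    patient_id: str,
    t0: dt.date,
    cci_category: str,
    outcome_end_date: dt.date = DEFAULT_END_OF_FOLLOWUP,
    attribution_end: dt.date | None = None,
) -> CohortRow:
    """Construct the analysis-ready survival row for one retained case.

    ``followup_days = min(death_date, outcome_end_date) - t0``;
    all-cause event iff death on or before the end of follow-up; the
    cancer-specific event additionally requires the death cause to be the
    target cancer (other-cause deaths censor that outcome at death).
    """
    pat = bundle.patients.loc[bundle.patients["patient_id"] == patient_id]
    if len(pat) != 1:
        raise ValidationError(f"patient {patient_id!r} not found exactly once")
    pat = pat.iloc[0]
    death_date = pat["death_date"]
    if pd.isna(death_date):
        death_date = None
    if death_date is not None and death_date < t0:
        raise ValidationError(
            f"patient {patient_id}: death {death_date} before study entry {t0}"
        )
    if death_date is not None and death_date <= outcome_end_date:
        end = death_date
        event_all = 1
        event_cancer = int(pat["death_cause"] == "target_cancer")
    else:
        end = outcome_end_date
        event_all = 0
        event_cancer = 0
    return CohortRow(
        patient_id=patient_id,
        time_zero=t0,
        followup_days=(end - t0).days,
        event_all_cause=event_all,
        event_cancer_specific=event_cancer,
        sex=pat["sex"],
        age_group=age_band(int(pat["birth_year"]), t0),
        treatment_category=derive_treatment_category(
            bundle, patient_id, t0, attribution_end
        ),
        cci_category=cci_category,
        split="unassigned",
    )


def build_cohort(
    bundle: ClaimsBundle,
    cci: Mapping[str, str] | pd.DataFrame,
    case_def: CaseDefinition = CaseDefinition(),
    washout: WashoutPolicy | None = None,
    outcome_end_date: dt.date = DEFAULT_END_OF_FOLLOWUP,
) -> pd.DataFrame:
    """Run the full cohort construction and return the cohort table.

    ``cci`` maps patient_id to a precomputed Charlson category ("0", "1-2",
    "3+"); a DataFrame with columns (patient_id, cci_category) is accepted.
    Patients younger than 15 at entry are dropped with a warning.
    """
    if washout is None:
        washout = WashoutPolicy(data_start=bundle.coverage_start)
    if isinstance(cci, pd.DataFrame):
        cci = dict(zip(cci["patient_id"], cci["cci_category"]))
    cases = apply_washout(identify_cases(bundle, case_def), washout)

    pat = bundle.patients.set_index("patient_id")
    tx = bundle.treatments.copy()
    tx["date"] = pd.to_datetime(tx["date"]).dt.date

    rows: list[CohortRow] = []
    underage: list[str] = []
    for pid, t0 in cases.itertuples(index=False):
        level = cci.get(pid)
        if level not in CCI_CATEGORIES:
            raise ValidationError(
                f"patient {pid}: missing or invalid CCI category {level!r}"
            )
        try:
            rows.append(
                build_survival_row(bundle, pid, t0, level, outcome_end_date)
            )
        except ValidationError as exc:
            if "below the 15-year minimum" in str(exc):
                underage.append(pid)
            else:
                raise
    if underage:
        warnings.warn(
            f"dropped {len(underage)} patient(s) younger than 15 at entry: "
            f"{underage[:5]}",
            stacklevel=2,
        )
    frame = pd.DataFrame(
        [
            (
                r.patient_id,
                r.time_zero,
                r.followup_days,
                r.event_all_cause,
                r.event_cancer_specific,
                r.sex,
                r.age_group,
                r.treatment_category,
                r.cci_category,
                r.split,
            )
            for r in rows
        ],
        columns=COHORT_COLUMNS,
    )
    return frame


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = cohort.copy()
    out["time_zero"] = out["time_zero"].map(
        lambda d: d.isoformat() if isinstance(d, dt.date) else str(d)
    )
    out.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["time_zero"] = pd.to_datetime(df["time_zero"]).dt.date
    return df
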