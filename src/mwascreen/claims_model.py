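"""Domain types for longitudinal claims data and analysis-ready survival rows.

The exchange format shared by every pipeline stage is a set of four linked
delimited tables (patients, diagnoses, treatments, prescriptions) plus a
small YAML sidecar carrying the data-coverage interval and the anticancer
ATC exclusion list.  All dates are ISO 8601 calendar dates and all durations
are whole days.

Tables are carried in memory as :class:`pandas.DataFrame` objects inside a
validated :class:`ClaimsBundle`; the per-record dataclasses exist for typed
row-wise construction and for documenting the schema invariants.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SEXES",
    "TREATMENT_KINDS",
    "AGE_BANDS",
    "TREATMENT_CATEGORIES",
    "CCI_CATEGORIES",
    "EXPOSURE_CLASSES",
    "SPLIT_LABELS",
    "DEATH_CAUSES",
    "ClaimsError",
    "SchemaError",
    "ReferentialIntegrityError",
    "ValidationError",
    "PatientRecord",
    "DiagnosisRecord",
    "TreatmentRecord",
    "PrescriptionRecord",
    "CohortRow",
    "ClaimsBundle",
    "read_claims_bundle",
    "write_claims_bundle",
    "validate_atc",
    "parse_date",
]

# Closed enumerations used across the pipeline.  Reference levels for model
# adjustment are always the first element of each tuple.
SEXES = ("male", "female")
TREATMENT_KINDS = ("colonoscopy", "operation", "chemotherapy", "radiotherapy")
AGE_BANDS = ("15-39", "40-49", "50-59", "60-69", "70-79", ">79")
TREATMENT_CATEGORIES = (
    "operation_only",
    "colonoscopy_only",
    "operation_chemo",
    "operation_radio",
    "operation_both",
    "chemo_or_radio_without_operation",
)
CCI_CATEGORIES = ("0", "1-2", "3+")
EXPOSURE_CLASSES = ("nonuser", "incident_user", "prevalent_user")
SPLIT_LABELS = ("unassigned", "discovery", "validation")
DEATH_CAUSES = ("target_cancer", "other")

# Full ATC code: letter, 2 digits, 2 letters, 2 digits (e.g. "N07AA02").
# Shorter prefixes at the classification-level cut points are accepted on
# input (lengths 1, 3, 4, 5).
_ATC_FULL = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
_ATC_PREFIX = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d{2}$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
}


class ClaimsError(Exception):
    """Base class for claims-data errors."""


class SchemaError(ClaimsError):
    """A table is missing a required column or has a malformed value."""


class ReferentialIntegrityError(ClaimsError):
    """An event row references a patient_id absent from the patients table."""


class ValidationError(ClaimsError):
    """A record or bundle violates a domain invariant."""


def validate_atc(code: str) -> str:
    """Validate an ATC code or level-prefix, returning it uppercased.

    Accepts a full 7-character code or any of the shorter hierarchy
    prefixes (1, 3, 4 or 5 characters).
    """
    if not isinstance(code, str):
        raise ValidationError(f"ATC code must be a string, got {code!r}")
    code = code.strip().upper()
    if _ATC_FULL.match(code):
        return code
    pat = _ATC_PREFIX.get(len(code))
    if pat is not None and pat.match(code):
        return code
    raise ValidationError(f"not a valid ATC code or prefix: {code!r}")


def parse_date(value, *, context: str = "") -> dt.date:
    """Parse an ISO 8601 calendar date, raising :class:`SchemaError` on failure."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        where = f" ({context})" if context else ""
        raise SchemaError(f"unparseable date {value!r}{where}") from exc


def _check_enum(value, allowed: Sequence[str], what: str):
    if value not in allowed:
        raise ValidationError(f"{what} must be one of {allowed}, got {value!r}")
    return value


@dataclass(frozen=True)
class PatientRecord:
    """One insured person: demographics plus (optional) death information.

    ``death_cause`` is pre-classified into ``target_cancer`` vs ``other`` at
    ingestion; mapping raw cause-of-death codes onto this binary is the data
    provider's (or the simulator's) responsibility.
    """

    patient_id: str
    sex: str
    birth_year: int
    death_date: dt.date | None = None
    death_cause: str | None = None

    def __post_init__(self):
        _check_enum(self.sex, SEXES, "sex")
        if (self.death_date is None) != (self.death_cause is None):
            raise ValidationError(
                f"patient {self.patient_id}: death_cause present iff death_date present"
            )
        if self.death_cause is not None:
            _check_enum(self.death_cause, DEATH_CAUSES, "death_cause")


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    date: dt.date
    code: str  # KCD/ICD-10 style, e.g. "C18", "C189"


@dataclass(frozen=True)
class TreatmentRecord:
    patient_id: str
    date: dt.date
    kind: str

    def __post_init__(self):
        _check_enum(self.kind, TREATMENT_KINDS, "treatment kind")


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    date: dt.date
    atc_code: str
    is_anticancer: bool = False

    def __post_init__(self):
        object.__setattr__(self, "atc_code", validate_atc(self.atc_code))


@dataclass
class CohortRow:
    """One analysis-ready record of the survival cohort.

    Cause-specific death (``event_cancer_specific``) implies all-cause death;
    patients dying of other causes are censored at death for the
    cancer-specific outcome, so the implication is asserted on construction.
    """

    patient_id: str
    time_zero: dt.date
    followup_days: int
    event_all_cause: int
    event_cancer_specific: int
    sex: str
    age_group: str
    treatment_category: str
    cci_category: str
    split: str = "unassigned"

    def __post_init__(self):
        if self.followup_days < 0:
            raise ValidationError(
                f"patient {self.patient_id}: followup_days must be >= 0"
            )
        if self.event_cancer_specific > self.event_all_cause:
            raise ValidationError(
                f"patient {self.patient_id}: cancer-specific death without all-cause death"
            )
        _check_enum(self.sex, SEXES, "sex")
        _check_enum(self.age_group, AGE_BANDS, "age_group")
        _check_enum(self.treatment_category, TREATMENT_CATEGORIES, "treatment_category")
        _check_enum(self.cci_category, CCI_CATEGORIES, "cci_category")
        _check_enum(self.split, SPLIT_LABELS, "split")


COHORT_COLUMNS = [
    "patient_id",
    "time_zero",
    "followup_days",
    "event_all_cause",
    "event_cancer_specific",
    "sex",
    "age_group",
    "treatment_category",
    "cci_category",
    "split",
]

_TABLE_COLUMNS: Mapping[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_year", "death_date", "death_cause"],
    "diagnoses": ["patient_id", "date", "code"],
    "treatments": ["patient_id", "date", "kind"],
    "prescriptions": ["patient_id", "date", "atc_code"],
}


@dataclass
class ClaimsBundle:
    """The four linked claims tables plus provenance metadata.

    Invariants enforced by :meth:`validate`:

    * every ``patient_id`` appearing in an event table exists in ``patients``;
    * all event dates (and death dates) lie inside
      ``[coverage_start, coverage_end]``;
    * per-record field invariants of the record dataclasses.

    ``prescriptions`` carries an ``is_anticancer`` column derived at
    construction from ``anticancer_atc_prefixes`` (prefix match on the raw
    ATC code); it is never serialized, only recomputed.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    treatments: pd.DataFrame
    prescriptions: pd.DataFrame
    coverage_start: dt.date
    coverage_end: dt.date
    anticancer_atc_prefixes: tuple[str, ...] = ()

    def __post_init__(self):
        self.anticancer_atc_prefixes = tuple(
            validate_atc(p) for p in self.anticancer_atc_prefixes
        )
        for name, cols in _TABLE_COLUMNS.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing column(s): {missing}")
            setattr(self, name, df.reset_index(drop=True))
        self._flag_anticancer()

    def _flag_anticancer(self) -> None:
        rx = self.prescriptions
        if self.anticancer_atc_prefixes and len(rx):
            flag = rx["atc_code"].str.upper().str.startswith(
                self.anticancer_atc_prefixes
            )
        else:
            flag = pd.Series(False, index=rx.index)
        self.prescriptions = rx.assign(is_anticancer=flag.astype(bool))

    # -- validation ---------------------------------------------------------
    def validate(self) -> "ClaimsBundle":
        if self.coverage_start > self.coverage_end:
            raise ValidationError("coverage_start after coverage_end")
        known = set(self.patients["patient_id"])
        if len(known) != len(self.patients):
            dupes = self.patients["patient_id"][
                self.patients["patient_id"].duplicated()
            ].tolist()
            raise ValidationError(f"duplicate patient_id(s): {dupes[:5]}")
        for name in ("diagnoses", "treatments", "prescriptions"):
            df = getattr(self, name)
            orphans = sorted(set(df["patient_id"]) - known)
            if orphans:
                raise ReferentialIntegrityError(
                    f"{name} references unknown patient_id(s): {orphans[:10]}"
                )
            if len(df):
                dates = pd.to_datetime(df["date"]).dt.date
                bad = df.loc[
                    (dates < self.coverage_start) | (dates > self.coverage_end)
                ]
                if len(bad):
                    raise ValidationError(
                        f"{name} has {len(bad)} event(s) outside coverage "
                        f"[{self.coverage_start}, {self.coverage_end}]"
                    )
        # per-patient invariants
        pat = self.patients
        has_date = pat["death_date"].notna()
        has_cause = pat["death_cause"].notna()
        if (has_date ^ has_cause).any():
            bad = pat.loc[has_date ^ has_cause, "patient_id"].tolist()
            raise ValidationError(
                f"death_cause present iff death_date present violated for {bad[:5]}"
            )
        if has_date.any():
            dd = pd.to_datetime(pat.loc[has_date, "death_date"]).dt.date
            if ((dd < self.coverage_start) | (dd > self.coverage_end)).any():
                raise ValidationError("death_date outside data coverage interval")
            bad_cause = ~pat.loc[has_cause, "death_cause"].isin(DEATH_CAUSES)
            if bad_cause.any():
                raise ValidationError("death_cause outside {target_cancer, other}")
        bad_sex = ~pat["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValidationError(
                f"invalid sex value(s): {pat.loc[bad_sex, 'sex'].unique().tolist()}"
            )
        bad_kind = ~self.treatments["kind"].isin(TREATMENT_KINDS)
        if len(self.treatments) and bad_kind.any():
            raise ValidationError(
                f"invalid treatment kind(s): "
                f"{self.treatments.loc[bad_kind, 'kind'].unique().tolist()}"
            )
        for code in self.prescriptions["atc_code"].unique():
            validate_atc(code)
        return self


# -- readers / writers ------------------------------------------------------

_META_NAME = "bundle_meta.yaml"
_DATE_COLS = {"patients": ["death_date"], "diagnoses": ["date"],
              "treatments": ["date"], "prescriptions": ["date"]}


def _parse_date_column(df: pd.DataFrame, table: str, col: str,
                       allow_missing: bool) -> pd.Series:
    out = []
    for i, raw in enumerate(df[col].tolist()):
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
            if allow_missing:
                out.append(None)
                continue
            raise SchemaError(f"{table}.csv line {i + 2}: missing {col}")
        try:
            out.append(dt.date.fromisoformat(str(raw).strip()))
        except ValueError as exc:
            raise SchemaError(
                f"{table}.csv line {i + 2}: unparseable date {raw!r} in {col}"
            ) from exc
    return pd.Series(out, index=df.index, dtype=object)


def read_claims_bundle(
    directory: str | Path | None = None,
    *,
    patients: str | Path | None = None,
    diagnoses: str | Path | None = None,
    treatments: str | Path | None = None,
    prescriptions: str | Path | None = None,
    meta: str | Path | None = None,
    sep: str = ",",
) -> ClaimsBundle:
    """Read a claims bundle from four delimited tables plus a metadata sidecar.

    Either pass ``directory`` containing ``patients.csv``/``diagnoses.csv``/
    ``treatments.csv``/``prescriptions.csv``/``bundle_meta.yaml``, or name
    each path explicitly.  If no sidecar exists the coverage interval is
    computed as the min/max over all event and death dates.
    """
    paths = {
        "patients": patients,
        "diagnoses": diagnoses,
        "treatments": treatments,
        "prescriptions": prescriptions,
    }
    if directory is not None:
        directory = Path(directory)
        for name in paths:
            if paths[name] is None:
                paths[name] = directory / f"{name}.csv"
        if meta is None and (directory / _META_NAME).exists():
            meta = directory / _META_NAME
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        if path is None:
            raise SchemaError(f"no path given for {name} table")
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        missing = [c for c in _TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} table missing column(s): {missing}")
        df = df[_TABLE_COLUMNS[name]].copy()
        df = df.replace({"": None})
        for col in _DATE_COLS[name]:
            df[col] = _parse_date_column(df, name, col,
                                         allow_missing=(name == "patients"))
        tables[name] = df
    tables["patients"]["birth_year"] = tables["patients"]["birth_year"].astype(int)

    anticancer: tuple[str, ...] = ()
    if meta is not None:
        with open(meta) as fh:
            m = yaml.safe_load(fh) or {}
        coverage_start = parse_date(m["coverage_start"], context=_META_NAME)
        coverage_end = parse_date(m["coverage_end"], context=_META_NAME)
        anticancer = tuple(m.get("anticancer_atc_prefixes", ()) or ())
    else:
        all_dates = [
            d
            for name in ("diagnoses", "treatments", "prescriptions")
            for d in tables[name]["date"]
        ] + [d for d in tables["patients"]["death_date"] if d is not None]
        if not all_dates:
            raise SchemaError(
                "no metadata sidecar and no event dates to infer coverage from"
            )
        coverage_start, coverage_end = min(all_dates), max(all_dates)

    bundle = ClaimsBundle(
        patients=tables["patients"],
        diagnoses=tables["diagnoses"],
        treatments=tables["treatments"],
        prescriptions=tables["prescriptions"],
        coverage_start=coverage_start,
        coverage_end=coverage_end,
        anticancer_atc_prefixes=anticancer,
    )
    return bundle.validate()


def write_claims_bundle(bundle: ClaimsBundle, directory: str | Path,
                        *, sep: str = ",") -> dict[str, Path]:
    """Write the four tables plus sidecar; inverse of :func:`read_claims_bundle`.

    The bundle is validated first; an invalid bundle is refused.
    """
    bundle.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, cols in _TABLE_COLUMNS.items():
        df = getattr(bundle, name)[cols].copy()
        for col in _DATE_COLS[name]:
            df[col] = df[col].map(lambda d: "" if d is None else d.isoformat())
        df = df.fillna("")
        path = directory / f"{name}.csv"
        df.to_csv(path, sep=sep, index=False)
        written[name] = path
    meta_path = directory / _META_NAME
    with open(meta_path, "w") as fh:
        yaml.safe_dump(
            {
                "coverage_start": bundle.coverage_start.isoformat(),
                "coverage_end": bundle.coverage_end.isoformat(),
                "anticancer_atc_prefixes": list(bundle.anticancer_atc_prefixes),
            },
            fh,
            sort_keys=False,
        )
    written["meta"] = meta_path
    return written


def bundle_from_records(
    patients: Iterable[PatientRecord],
    diagnoses: Iterable[DiagnosisRecord],
    treatments: Iterable[TreatmentRecord],
    prescriptions: Iterable[PrescriptionRecord],
    coverage_start: dt.date,
    coverage_end: dt.date,
    anticancer_atc_prefixes: Sequence[str] = (),
) -> ClaimsBundle:
    """Assemble a validated bundle from typed record objects."""
    pat = pd.DataFrame(
        [(p.patient_id, p.sex, p.birth_year, p.death_date, p.death_cause)
         for p in patients],
        columns=_TABLE_COLUMNS["patients"],
    )
    dx = pd.DataFrame(
        [(d.patient_id, d.date, d.code) for d in diagnoses],
        columns=_TABLE_COLUMNS["diagnoses"],
    )
    tx = pd.DataFrame(
        [(t.patient_id, t.date, t.kind) for t in treatments],
        columns=_TABLE_COLUMNS["treatments"],
    )
    rx = pd.DataFrame(
        [(r.patient_id, r.date, r.atc_code) for r in prescriptions],
        columns=_TABLE_COLUMNS["prescriptions"],
    )
    return ClaimsBundle(
        patients=pat, diagnoses=dx, treatments=tx, prescriptions=rx,
        coverage_start=coverage_start, coverage_end=coverage_end,
        anticancer_atc_prefixes=tuple(anticancer_atc_prefixes),
    ).validate()
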