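"""Past-1-year incident-user exposure classification at ATC levels 2 and 4.

Exposure is defined entirely before study entry (time zero, the date of
first cancer treatment), which makes time zero a landmark and removes
immortal-time bias by construction.  Relative to time zero ``t0`` and with
the default windows, a patient-drug pair is classified from its
prescription dates as:

* ``prevalent_user`` — any prescription in the far window
  ``[t0 - 548 d, t0 - 365 d)``, regardless of later use;
* ``incident_user`` — otherwise, at least one prescription in the near
  window ``[t0 - 365 d, t0)``;
* ``nonuser`` — no prescription anywhere in ``[t0 - 548 d, t0)``.

Windows are half-open at day resolution; prescriptions on or after ``t0``
or before the far boundary are ignored.  Prevalent users are excluded from
that drug's model downstream (the screen compares incident users with
nonusers); a config switch allows recoding them as nonusers for sensitivity
analysis.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .claims_model import (
    EXPOSURE_CLASSES,
    ClaimsBundle,
    ValidationError,
    validate_atc,
)

__all__ = [
    "ExposureWindows",
    "ExposureMatrix",
    "truncate_atc",
    "classify_exposure",
    "build_exposure_matrix",
]

logger = logging.getLogger(__name__)

#: prefix length per ATC classification level
ATC_LEVEL_LENGTH = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


@dataclass(frozen=True)
class ExposureWindows:
    """Lookback windows in whole days (1 year = 365 d, 1.5 years = 548 d)."""

    lookback_far_days: int = 548
    lookback_near_days: int = 365

    def __post_init__(self):
        if not self.lookback_far_days > self.lookback_near_days > 0:
            raise ValidationError(
                "need lookback_far_days > lookback_near_days > 0, got "
                f"{self.lookback_far_days}/{self.lookback_near_days}"
            )


def truncate_atc(code: str, level: int) -> str:
    """Truncate an ATC code to the prefix of the given classification level.

    Level 2 keeps 3 characters (therapeutic group, e.g. ``N07AA02 -> N07``),
    level 4 keeps 5 (chemical subgroup, e.g. ``A02AA04 -> A02AA``).
    """
    if level not in ATC_LEVEL_LENGTH:
        raise ValidationError(f"unknown ATC level {level!r}")
    code = validate_atc(code)
    n = ATC_LEVEL_LENGTH[level]
    if len(code) < n:
        raise ValidationError(
            f"ATC code {code!r} too short to truncate to level {level} "
            f"({n} characters required)"
        )
    return code[:n]


def classify_exposure(
    prescription_dates: Iterable[dt.date],
    t0: dt.date,
    windows: ExposureWindows = ExposureWindows(),
) -> str:
    """Classify one patient-drug pair from its pooled prescription dates.

    Far-window use takes precedence: any prescription in the far window
    makes the pair a prevalent user even when later prescriptions fall in
    the near window.  Prescriptions outside ``[t0 - far, t0)`` are ignored
    (post-entry use is outside the exposure definition).
    """
    far_start = t0 - dt.timedelta(days=windows.lookback_far_days)
    near_start = t0 - dt.timedelta(days=windows.lookback_near_days)
    in_far = in_near = False
    for d in prescription_dates:
        if d >= t0:
            logger.debug("ignoring post-entry prescription on %s (t0=%s)", d, t0)
            continue
        if d < far_start:
            continue
        if d < near_start:
            in_far = True
        else:
            in_near = True
    if in_far:
        return "prevalent_user"
    if in_near:
        return "incident_user"
    return "nonuser"


@dataclass
class ExposureMatrix:
    """Per-(patient, drug) exposure classes at one ATC level.

    ``frame`` is a wide DataFrame indexed by ``patient_id`` with one column
    per truncated drug code; every cell holds exactly one of the three
    class labels (the classes partition the pairs).
    """

    atc_level: int
    drugs: list[str]
    frame: pd.DataFrame

    def __post_init__(self):
        if len(set(self.drugs)) != len(self.drugs):
            raise ValidationError("duplicate drug codes in exposure matrix")
        n = ATC_LEVEL_LENGTH[self.atc_level]
        bad = [d for d in self.drugs if len(d) != n]
        if bad:
            raise ValidationError(
                f"drug codes not at level-{self.atc_level} length {n}: {bad[:5]}"
            )
        if list(self.frame.columns) != list(self.drugs):
            raise ValidationError("frame columns must equal the drug list")
        vals = self.frame.to_numpy()
        if vals.size and not np.isin(vals, EXPOSURE_CLASSES).all():
            raise ValidationError("exposure classes outside the enumeration")

    def classes_for(self, drug: str) -> pd.Series:
        return self.frame[drug]

    def to_long(self) -> pd.DataFrame:
        long = (
            self.frame.stack()
            .rename_axis(["patient_id", "drug"])
            .rename("class")
            .reset_index()
        )
        return long.sort_values(["patient_id", "drug"]).reset_index(drop=True)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long().to_csv(path, index=False)
        return path

    @classmethod
    def from_long(cls, long: pd.DataFrame, atc_level: int) -> "ExposureMatrix":
        frame = long.pivot(index="patient_id", columns="drug", values="class")
        frame = frame.sort_index(axis=1)
        frame.columns.name = None
        return cls(atc_level=atc_level, drugs=list(frame.columns), frame=frame)

    @classmethod
    def read_csv(cls, path: str | Path, atc_level: int) -> "ExposureMatrix":
        return cls.from_long(pd.read_csv(path, dtype=str), atc_level)


def build_exposure_matrix(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    level: int,
    windows: ExposureWindows = ExposureWindows(),
    anticancer_prefixes: Sequence[str] | None = None,
    min_users: int = 1,
) -> ExposureMatrix:
    """Build the (patient x drug) exposure matrix for one ATC level.

    Prescriptions flagged anticancer (by ``bundle.anticancer_atc_prefixes``
    or the explicit ``anticancer_prefixes`` override) are dropped first,
    remaining codes are truncated to the level, the dates of all codes
    sharing a truncated prefix are pooled per patient, and each pair is
    classified.  The drug list keeps the distinct truncated codes with at
    least ``min_users`` incident users in the given cohort.
    """
    if cohort is None or len(cohort) == 0:
        raise ValidationError("empty cohort: build the cohort before exposure")
    if level not in (2, 4):
        raise ValidationError(f"exposure is screened at ATC level 2 or 4, got {level}")

    t0 = pd.to_datetime(cohort.set_index("patient_id")["time_zero"])
    rx = bundle.prescriptions
    if anticancer_prefixes is not None:
        prefixes = tuple(validate_atc(p) for p in anticancer_prefixes)
        flag = (
            rx["atc_code"].str.upper().str.startswith(prefixes)
            if prefixes
            else pd.Series(False, index=rx.index)
        )
        rx = rx.loc[~flag]
    else:
        rx = rx.loc[~rx["is_anticancer"]]
    rx = rx.loc[rx["patient_id"].isin(t0.index)]

    patients = t0.index.to_list()
    if len(rx) == 0:
        return ExposureMatrix(
            atc_level=level,
            drugs=[],
            frame=pd.DataFrame(index=pd.Index(patients, name="patient_id")),
        )

    n = ATC_LEVEL_LENGTH[level]
    work = pd.DataFrame(
        {
            "patient_id": rx["patient_id"].to_numpy(),
            "drug": rx["atc_code"].str.upper().str[:n].to_numpy(),
            "date": pd.to_datetime(rx["date"]).to_numpy(),
        }
    )
    too_short = rx["atc_code"].str.len() < n
    if too_short.any():
        bad = rx.loc[too_short, "atc_code"].unique().tolist()
        raise ValidationError(
            f"ATC code(s) too short for level {level}: {bad[:5]}"
        )
    work["t0"] = work["patient_id"].map(t0)
    delta = (work["t0"] - work["date"]).dt.days  # days before entry
    work["in_far"] = (delta > windows.lookback_near_days) & (
        delta <= windows.lookback_far_days
    )
    work["in_near"] = (delta >= 1) & (delta <= windows.lookback_near_days)
    agg = work.groupby(["patient_id", "drug"], sort=True)[["in_far", "in_near"]].any()
    cls = np.where(
        agg["in_far"], "prevalent_user", np.where(agg["in_near"], "incident_user", "nonuser")
    )
    long = agg.reset_index()[["patient_id", "drug"]].assign(**{"class": cls})

    incident_counts = (
        long["class"].eq("incident_user").groupby(long["drug"]).sum()
    )
    drugs = sorted(incident_counts[incident_counts >= min_users].index)

    frame = pd.DataFrame(
        "nonuser", index=pd.Index(patients, name="patient_id"), columns=drugs
    )
    keep = long.loc[long["drug"].isin(drugs)]
    if len(keep):
        wide = keep.pivot(index="patient_id", columns="drug", values="class")
        frame.update(wide)
    frame = frame.loc[patients]
    return ExposureMatrix(atc_level=level, drugs=drugs, frame=frame)
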