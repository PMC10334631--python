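"""The medication-wide association screen.

The cohort is split 1:1 at random into a drug discovery set and a drug
validation set.  In the discovery set every eligible drug is tested with a
covariate-adjusted Cox proportional-hazards model (binary incident-user
indicator vs nonuser; prevalent users excluded from that drug's model),
and the per-family p-values are corrected with the Benjamini-Hochberg
step-up procedure at a 5% false discovery rate.  One multiplicity family
is formed per outcome x ATC level, matching one volcano plot each.
Discovery signals are then refit in the validation set and count as
validated when the validation p-value is below 0.05 (two-sided Wald) and,
by default, the effect direction agrees across the two stages.

Cause-specific mortality is analyzed with cause-specific hazards: deaths
from other causes censor the cancer-specific outcome at the date of death.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .claims_model import (
    AGE_BANDS,
    CCI_CATEGORIES,
    SEXES,
    TREATMENT_CATEGORIES,
    ValidationError,
)
from .coxph import fit_coxph
from .exposure import ExposureMatrix

__all__ = [
    "ScreenConfig",
    "DrugScreenResult",
    "ScreenReport",
    "split_cohort",
    "fit_drug_model",
    "bh_adjust",
    "run_two_stage_screen",
]

OUTCOMES = ("all_cause", "cancer_specific")
_EVENT_COLUMN = {
    "all_cause": "event_all_cause",
    "cancer_specific": "event_cancer_specific",
}

#: fixed reference level = first element of each enumeration
_ADJUSTMENT_LEVELS = {
    "sex": SEXES,
    "age_group": AGE_BANDS,
    "treatment_category": TREATMENT_CATEGORIES,
    "cci_category": CCI_CATEGORIES,
}

RESULT_COLUMNS = [
    "drug", "level", "outcome", "stage", "n_users", "n_nonusers", "n_events",
    "log_hr", "hr", "ci_low", "ci_high", "p_raw", "p_fdr_adjusted",
    "converged", "reason", "validated",
]


@dataclass
class ScreenConfig:
    """Tuning knobs of the two-stage screen (defaults follow the study design)."""

    fdr_q: float = 0.05
    validation_alpha: float = 0.05
    split_ratio: float = 0.5
    split_seed: int = 0
    adjustment_set: tuple[str, ...] = (
        "sex", "age_group", "treatment_category", "cci_category"
    )
    outcomes: tuple[str, ...] = OUTCOMES
    ties_method: str = "efron"
    require_direction_consistency: bool = True
    min_users_per_arm: int = 10
    prevalent_handling: str = "exclude"   # or "recode_nonuser" (sensitivity)
    fdr_method: str = "bh"                # or "by" (sensitivity)

    def __post_init__(self):
        if not 0 < self.fdr_q < 1:
            raise ValidationError("fdr_q must be in (0,1)")
        if not 0 < self.split_ratio < 1:
            raise ValidationError("split_ratio must be in (0,1)")
        if self.ties_method not in ("efron", "breslow"):
            raise ValidationError("ties_method must be 'efron' or 'breslow'")
        if self.prevalent_handling not in ("exclude", "recode_nonuser"):
            raise ValidationError(
                "prevalent_handling must be 'exclude' or 'recode_nonuser'"
            )
        if self.fdr_method not in ("bh", "by"):
            raise ValidationError("fdr_method must be 'bh' or 'by'")
        unknown = set(self.adjustment_set) - set(_ADJUSTMENT_LEVELS)
        if unknown:
            raise ValidationError(f"unknown adjustment covariates: {sorted(unknown)}")
        bad = set(self.outcomes) - set(OUTCOMES)
        if bad:
            raise ValidationError(f"unknown outcomes: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("adjustment_set", "outcomes"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        d = dict(d)
        for key in ("adjustment_set", "outcomes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class DrugScreenResult:
    """One drug x outcome x stage Cox fit."""

    drug: str
    outcome: str
    stage: str
    n_users: int
    n_nonusers: int
    n_events: int
    log_hr: float = np.nan
    hr: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_raw: float = np.nan
    p_fdr_adjusted: float = np.nan
    converged: bool = False
    reason: str = ""

    def __post_init__(self):
        if self.converged:
            if not (self.hr > 0 and self.ci_low <= self.hr <= self.ci_high):
                raise ValidationError(
                    f"{self.drug}/{self.outcome}/{self.stage}: CI must bracket HR"
                )
            if not 0 <= self.p_raw <= 1:
                raise ValidationError("p value outside [0,1]")


@dataclass
class ScreenReport:
    """Assembled two-stage screen: full table plus the signal lists.

    ``discovery_signals`` and ``validated_signals`` hold (level, outcome,
    drug) triples; validated signals are always a subset of discovery
    signals, and a signal's direction is protective iff its hazard ratio
    is below 1 in both stages.
    """

    results: pd.DataFrame
    discovery_signals: list[tuple[int, str, str]]
    validated_signals: list[tuple[int, str, str]]
    directions: dict[tuple[int, str, str], str]
    config: ScreenConfig


def split_cohort(
    cohort: pd.DataFrame, ratio: float = 0.5, seed: int = 0
) -> pd.DataFrame:
    """Label each row 'discovery' or 'validation' by simple random split.

    ``|discovery| = round(ratio * n)`` (banker's rounding); deterministic
    given the seed and invariant to the row order of ``cohort``.
    """
    n = len(cohort)
    if n < 2:
        raise ValidationError("need at least 2 rows to split")
    if not 0 < ratio < 1:
        raise ValidationError("split ratio must be in (0,1)")
    n_disc = int(round(ratio * n))
    rng = np.random.default_rng(seed)
    order = np.argsort(cohort["patient_id"].to_numpy(), kind="stable")
    picked = rng.permutation(n)[:n_disc]
    labels = np.full(n, "validation", dtype=object)
    labels[picked] = "discovery"
    out = cohort.copy()
    out.loc[out.index[order], "split"] = labels
    return out


def _design_matrix(rows: pd.DataFrame, adjustment_set: Sequence[str]) -> np.ndarray:
    cols = []
    for name in adjustment_set:
        levels = _ADJUSTMENT_LEVELS[name]
        vals = rows[name].to_numpy()
        for lv in levels[1:]:  # first level is the reference
            cols.append((vals == lv).astype(float))
    if not cols:
        return np.empty((len(rows), 0))
    return np.column_stack(cols)


def _fit_indicator(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    design: np.ndarray,
    config: ScreenConfig,
    base: dict,
) -> DrugScreenResult:
    """Array-level core of the per-drug fit; inputs already row-filtered."""
    n_users = int(x.sum())
    n_nonusers = int(x.size - n_users)
    n_events = int(event.sum())
    base = dict(base, n_users=n_users, n_nonusers=n_nonusers, n_events=n_events)
    if n_users == 0 or n_nonusers == 0:
        return DrugScreenResult(**base, reason="degenerate exposure")
    if min(n_users, n_nonusers) < config.min_users_per_arm:
        return DrugScreenResult(**base, reason="below min_users_per_arm")
    if n_events == 0:
        return DrugScreenResult(**base, reason="no events")
    X = np.column_stack([x, design])
    # drop adjustment columns with no variation in this subset (keep the
    # drug indicator in position 0)
    keep = np.r_[True, X[:, 1:].std(axis=0) > 0]
    X = X[:, keep]
    try:
        fit = fit_coxph(time, event, X, ties=config.ties_method)
    except Exception as exc:  # fit must never abort the screen
        return DrugScreenResult(**base, reason=f"fit error: {exc}")
    if not fit.converged:
        return DrugScreenResult(**base, reason="did not converge")
    b, se, lo, hi, p = fit.summary_for(0)
    return DrugScreenResult(
        **base, log_hr=b, hr=float(np.exp(b)), ci_low=lo, ci_high=hi,
        p_raw=p, converged=True,
    )


def fit_drug_model(
    rows: pd.DataFrame,
    exposure: pd.Series | np.ndarray,
    outcome: str,
    config: ScreenConfig,
    stage: str = "discovery",
    drug: str = "",
) -> DrugScreenResult:
    """Adjusted Cox fit of one outcome on one drug's incident-user indicator.

    ``rows`` is one split of the cohort with prevalent users for this drug
    already excluded; ``exposure`` is the aligned 0/1 indicator.  Degenerate
    exposure (all one class) or a failed fit yields ``converged=False``
    with a reason — the screen continues over the remaining drugs.
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}")
    x = np.asarray(exposure, dtype=float)
    if x.shape[0] != len(rows):
        raise ValidationError("exposure vector not aligned with rows")
    return _fit_indicator(
        rows["followup_days"].to_numpy(dtype=float),
        rows[_EVENT_COLUMN[outcome]].to_numpy(dtype=np.int64),
        x,
        _design_matrix(rows, config.adjustment_set),
        config,
        dict(drug=drug, outcome=outcome, stage=stage),
    )


def bh_adjust(
    p_values: Sequence[float], q: float = 0.05, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    With order statistics p(1) <= ... <= p(m), all hypotheses i <= k are
    rejected where k = max{i : p(i) <= i q / m}; the adjusted value is
    ``p_adj(i) = min(1, min_{j >= i} m p(j) / j)`` so that the rejection
    flags coincide with ``p_adj <= q``.  NaN entries (unconverged fits
    carrying no test) are excluded from m and returned as NaN/False.
    ``method='by'`` applies the Benjamini-Yekutieli correction factor.
    """
    p = np.asarray(p_values, dtype=float)
    nan = np.isnan(p)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p values must lie in [0,1]")
    adjusted = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    pv = p[~nan]
    m = pv.size
    if m == 0:
        return adjusted, reject
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    c = np.sum(1.0 / np.arange(1, m + 1)) if method == "by" else 1.0
    raw = c * m * ranked / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    adjusted[~nan] = out
    reject[~nan] = out <= q
    return adjusted, reject


def run_two_stage_screen(
    cohort: pd.DataFrame,
    matrices: Mapping[int, ExposureMatrix],
    config: ScreenConfig = ScreenConfig(),
) -> ScreenReport:
    """Run the full discovery/validation screen over every level and outcome.

    The cohort must carry split labels (see :func:`split_cohort`); rows
    labelled ``unassigned`` are ignored.  Returns the assembled report with
    the per-drug audit trail (eligibility, convergence, both stages).
    """
    if "split" not in cohort.columns or (cohort["split"] == "unassigned").all():
        raise ValidationError("cohort is not split; call split_cohort first")
    disc = cohort.loc[cohort["split"] == "discovery"]
    val = cohort.loc[cohort["split"] == "validation"]

    all_rows: list[dict] = []
    discovery_signals: list[tuple[int, str, str]] = []
    validated_signals: list[tuple[int, str, str]] = []
    directions: dict[tuple[int, str, str], str] = {}

    # per-split arrays shared by every drug fit
    prep = {
        "discovery": _prep_split(disc, config),
        "validation": _prep_split(val, config),
    }

    for level in sorted(matrices):
        matrix = matrices[level]
        disc_classes = matrix.frame.reindex(disc["patient_id"]).to_numpy()
        val_classes = matrix.frame.reindex(val["patient_id"]).to_numpy()
        for outcome in config.outcomes:
            stage_results: list[DrugScreenResult] = []
            for j, drug in enumerate(matrix.drugs):
                stage_results.append(
                    _fit_from_classes(
                        prep["discovery"], disc_classes[:, j], outcome,
                        config, "discovery", drug,
                    )
                )
            pvals = [
                r.p_raw if r.converged else np.nan for r in stage_results
            ]
            adjusted, reject = bh_adjust(pvals, config.fdr_q, config.fdr_method)
            for r, a in zip(stage_results, adjusted):
                r.p_fdr_adjusted = float(a) if np.isfinite(a) else np.nan

            for r, rej in zip(stage_results, reject):
                row = dataclasses.asdict(r)
                row.update(level=level, validated=False)
                if not rej:
                    all_rows.append(row)
                    continue
                key = (level, outcome, r.drug)
                discovery_signals.append(key)
                jdx = matrix.drugs.index(r.drug)
                vres = _fit_from_classes(
                    prep["validation"], val_classes[:, jdx], outcome,
                    config, "validation", r.drug,
                )
                ok = bool(
                    vres.converged and vres.p_raw < config.validation_alpha
                )
                if ok and config.require_direction_consistency:
                    ok = np.sign(vres.log_hr) == np.sign(r.log_hr)
                if ok:
                    validated_signals.append(key)
                    if r.hr < 1 and vres.hr < 1:
                        directions[key] = "protective"
                    elif r.hr > 1 and vres.hr > 1:
                        directions[key] = "detrimental"
                    else:
                        directions[key] = "inconsistent"
                row["validated"] = ok
                all_rows.append(row)
                vrow = dataclasses.asdict(vres)
                vrow.update(level=level, validated=ok)
                all_rows.append(vrow)

    if not any(matrices[lv].drugs for lv in matrices):
        warnings.warn("no eligible drugs: returning an empty screen report",
                      stacklevel=2)
    results = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
    if len(results):
        results = results.sort_values(
            ["level", "outcome", "drug", "stage"],
            kind="stable",
        ).reset_index(drop=True)
    return ScreenReport(
        results=results,
        discovery_signals=sorted(set(discovery_signals)),
        validated_signals=sorted(set(validated_signals)),
        directions=directions,
        config=config,
    )


def _drug_rows(split_rows: pd.DataFrame, classes: pd.Series, config: ScreenConfig):
    """Apply the prevalent-user policy; return (rows, 0/1 exposure vector)."""
    cls = classes.to_numpy()
    if config.prevalent_handling == "exclude":
        keep = cls != "prevalent_user"
        rows = split_rows.loc[keep]
        x = (cls[keep] == "incident_user").astype(float)
    else:
        rows = split_rows
        x = (cls == "incident_user").astype(float)
    return rows, x


def _prep_split(rows: pd.DataFrame, config: ScreenConfig) -> dict:
    return {
        "time": rows["followup_days"].to_numpy(dtype=float),
        "events": {
            oc: rows[_EVENT_COLUMN[oc]].to_numpy(dtype=np.int64)
            for oc in config.outcomes
        },
        "design": _design_matrix(rows, config.adjustment_set),
    }


def _fit_from_classes(
    prep: dict,
    cls: np.ndarray,
    outcome: str,
    config: ScreenConfig,
    stage: str,
    drug: str,
) -> DrugScreenResult:
    base = dict(drug=drug, outcome=outcome, stage=stage)
    if config.prevalent_handling == "exclude":
        keep = cls != "prevalent_user"
        if keep.all():
            x = (cls == "incident_user").astype(float)
            return _fit_indicator(
                prep["time"], prep["events"][outcome], x, prep["design"],
                config, base,
            )
        x = (cls[keep] == "incident_user").astype(float)
        return _fit_indicator(
            prep["time"][keep], prep["events"][outcome][keep], x,
            prep["design"][keep], config, base,
        )
    x = (cls == "incident_user").astype(float)
    return _fit_indicator(
        prep["time"], prep["events"][outcome], x, prep["design"], config, base
    )


def write_results(results: pd.DataFrame, path) -> None:
    out = results.copy()
    float_cols = ["log_hr", "hr", "ci_low", "ci_high", "p_raw", "p_fdr_adjusted"]
    for c in float_cols:
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.10g}")
    out.to_csv(path, index=False)
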