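import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwascreen.claims_model import ValidationError
from mwascreen.cohort_builder import build_cohort
from mwascreen.exposure import (
    ExposureMatrix,
    ExposureWindows,
    build_exposure_matrix,
    classify_exposure,
    truncate_atc,
)
from mwascreen.synthetic_claims import simulate_bundle

T0 = dt.date(2010, 6, 15)


def oracle_classify(dates, t0, far=548, near=365):
    """Brute-force day-by-day window scan, independent of the implementation."""
    far_days = {t0 - dt.timedelta(days=d) for d in range(near + 1, far + 1)}
    near_days = {t0 - dt.timedelta(days=d) for d in range(1, near + 1)}
    dates = set(dates)
    if dates & far_days:
        return "prevalent_user"
    if dates & near_days:
        return "incident_user"
    return "nonuser"


class TestTruncateAtc:
    @pytest.mark.parametrize(
        "code,level,expected",
        [
            ("N07AA02", 2, "N07"),
            ("A02AA04", 4, "A02AA"),
            ("B01AC06", 4, "B01AC"),
            ("n07aa02", 2, "N07"),
            ("N07AA", 4, "N07AA"),
        ],
    )
    def test_truncation(self, code, level, expected):
        assert truncate_atc(code, level) == expected

    def test_code_too_short_is_named(self):
        with pytest.raises(ValidationError, match="N07"):
            truncate_atc("N07", 4)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValidationError):
            truncate_atc("N07AA02", 7)


class TestClassifyExposure:
    @pytest.mark.parametrize(
        "offsets,expected",
        [
            ([100], "incident_user"),
            ([400], "prevalent_user"),
            ([], "nonuser"),
            ([400, 30], "prevalent_user"),   # far use takes precedence
            ([365], "incident_user"),        # near boundary inclusive
            ([366], "prevalent_user"),
            ([548], "prevalent_user"),       # far boundary inclusive
            ([549], "nonuser"),              # beyond the lookback
            ([0], "nonuser"),                # on entry day: post-entry
            ([-50], "nonuser"),              # after entry
        ],
    )
    def test_window_boundaries(self, offsets, expected):
        dates = [T0 - dt.timedelta(days=d) for d in offsets]
        assert classify_exposure(dates, T0) == expected

    def test_agrees_with_window_scan_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = rng.integers(0, 6)
            offsets = rng.integers(-100, 700, size=n)
            dates = [T0 - dt.timedelta(days=int(d)) for d in offsets]
            assert classify_exposure(dates, T0) == oracle_classify(dates, T0)

    @given(st.lists(st.integers(min_value=-100, max_value=700), max_size=8),
           st.integers(min_value=366, max_value=548))
    @settings(max_examples=200, deadline=None)
    def test_far_prescription_forces_prevalent(self, offsets, far_offset):
        """Adding a far-window prescription can only move a pair toward
        prevalent, never away."""
        dates = [T0 - dt.timedelta(days=d) for d in offsets]
        with_far = dates + [T0 - dt.timedelta(days=far_offset)]
        assert classify_exposure(with_far, T0) == "prevalent_user"

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValidationError):
            ExposureWindows(lookback_far_days=365, lookback_near_days=365)


class TestBuildExposureMatrix:
    @pytest.fixture
    def pipeline(self, small_sim_config):
        bundle, cov, truth = simulate_bundle(small_sim_config)
        cohort = build_cohort(bundle, cov[["patient_id", "cci_category"]])
        return bundle, cohort, truth

    def test_partition_exactly_one_class_per_pair(self, pipeline):
        bundle, cohort, _ = pipeline
        matrix = build_exposure_matrix(bundle, cohort, 4)
        assert matrix.frame.isin(
            ["nonuser", "incident_user", "prevalent_user"]
        ).all().all()
        assert len(matrix.frame) == len(cohort)

    def test_level2_pools_level4_dates(self, pipeline):
        """Classifying at level 2 equals classifying the union of the
        patient's level-4 prescription dates sharing the 3-char prefix."""
        bundle, cohort, _ = pipeline
        m2 = build_exposure_matrix(bundle, cohort, 2)
        rx = bundle.prescriptions
        rx = rx.loc[~rx["is_anticancer"]]
        t0 = cohort.set_index("patient_id")["time_zero"]
        rng = np.random.default_rng(3)
        pids = rng.choice(cohort["patient_id"], size=40, replace=False)
        for pid in pids:
            for drug in m2.drugs:
                dates = rx.loc[
                    (rx["patient_id"] == pid)
                    & (rx["atc_code"].str.startswith(drug)),
                    "date",
                ].tolist()
                assert m2.frame.at[pid, drug] == oracle_classify(dates, t0[pid])

    def test_no_post_entry_leakage(self, pipeline):
        """Deleting all prescriptions on/after entry leaves the matrix
        unchanged (exposure is fully pre-landmark)."""
        bundle, cohort, _ = pipeline
        before = build_exposure_matrix(bundle, cohort, 4)
        t0 = cohort.set_index("patient_id")["time_zero"]
        rx = bundle.prescriptions
        entry = rx["patient_id"].map(t0)
        mask = pd.Series(
            [d < e for d, e in zip(rx["date"], entry)], index=rx.index
        )
        bundle.prescriptions = rx.loc[mask].reset_index(drop=True)
        after = build_exposure_matrix(bundle, cohort, 4)
        assert before.frame.equals(after.frame)

    def test_anticancer_only_bundle_gives_empty_drug_list(
            self, tiny_bundle):
        tiny_bundle.prescriptions = pd.DataFrame(
            {
                "patient_id": ["P001", "P001"],
                "date": [dt.date(2004, 12, 1), dt.date(2005, 1, 2)],
                "atc_code": ["L01BC06", "L02AB01"],
            }
        )
        tiny_bundle._flag_anticancer()
        cohort = pd.DataFrame(
            {"patient_id": ["P001"], "time_zero": [dt.date(2005, 3, 1)]}
        )
        matrix = build_exposure_matrix(tiny_bundle, cohort, 4)
        assert matrix.drugs == []

    def test_empty_cohort_rejected(self, tiny_bundle):
        with pytest.raises(ValidationError, match="empty cohort"):
            build_exposure_matrix(tiny_bundle, pd.DataFrame(), 4)

    def test_level2_merges_sibling_codes(self, tiny_bundle):
        # P001 has N07AA02 (near window) and we add N07AB01 in the far window
        extra = pd.DataFrame(
            {
                "patient_id": ["P001"],
                "date": [dt.date(2004, 2, 1)],
                "atc_code": ["N07AB01"],
            }
        )
        tiny_bundle.prescriptions = pd.concat(
            [tiny_bundle.prescriptions.drop(columns="is_anticancer"), extra],
            ignore_index=True,
        )
        tiny_bundle._flag_anticancer()
        cohort = pd.DataFrame(
            {"patient_id": ["P001"], "time_zero": [dt.date(2005, 3, 1)]}
        )
        m2 = build_exposure_matrix(tiny_bundle, cohort, 2, min_users=0)
        # pooled dates: 2005-01-15 (near, 45 d) + 2004-02-01 (far, 394 d):
        # far use takes precedence over the sibling code's near use
        assert m2.frame.at["P001", "N07"] == "prevalent_user"

    def test_long_csv_round_trip(self, pipeline, tmp_path):
        bundle, cohort, _ = pipeline
        matrix = build_exposure_matrix(bundle, cohort, 4)
        path = matrix.write_csv(tmp_path / "exposure_L4.csv")
        back = ExposureMatrix.read_csv(path, 4)
        assert back.frame.sort_index().equals(matrix.frame.sort_index())
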