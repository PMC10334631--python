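import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwascreen.claims_model import ValidationError
from mwascreen.screening import (
    ScreenConfig,
    bh_adjust,
    fit_drug_model,
    run_two_stage_screen,
    split_cohort,
)
from mwascreen.synthetic_claims import (
    DrugSpec,
    default_config,
    high_mortality_config,
    simulate_analysis_frame,
)


def bh_oracle(pvals, q):
    """Exhaustive step-up oracle: evaluate the rejection rule at every
    candidate k instead of using the adjusted-p shortcut."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    k = 0
    for i in range(1, m + 1):
        if ranked[i - 1] <= i * q / m:
            k = i
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    adjusted = np.empty(m)
    for i in range(m):
        adjusted[order[i]] = min(
            1.0, min(m * ranked[j] / (j + 1) for j in range(i, m))
        )
    return adjusted, reject


class TestSplitCohort:
    def _cohort(self, n):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i:05d}" for i in range(n)],
                "split": "unassigned",
            }
        )

    def test_even_cohort_splits_in_halves(self):
        out = split_cohort(self._cohort(2618), 0.5, seed=1)
        counts = out["split"].value_counts()
        assert counts["discovery"] == 1309 and counts["validation"] == 1309

    def test_odd_cohort_rounding(self):
        out = split_cohort(self._cohort(5), 0.5, seed=1)
        sizes = set(out["split"].value_counts())
        assert sizes == {2, 3}

    def test_same_seed_reproduces_labels(self):
        a = split_cohort(self._cohort(100), 0.5, seed=9)
        b = split_cohort(self._cohort(100), 0.5, seed=9)
        assert a["split"].tolist() == b["split"].tolist()

    def test_labels_attach_to_patients_not_positions(self):
        cohort = self._cohort(100)
        a = split_cohort(cohort, 0.5, seed=9).set_index("patient_id")["split"]
        shuffled = cohort.sample(frac=1, random_state=0).reset_index(drop=True)
        b = split_cohort(shuffled, 0.5, seed=9).set_index("patient_id")["split"]
        assert a.sort_index().equals(b.sort_index())

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            split_cohort(self._cohort(1), 0.5, seed=0)


class TestBhAdjust:
    def test_worked_example(self):
        adjusted, reject = bh_adjust([0.005, 0.01, 0.03, 0.04], q=0.05)
        np.testing.assert_allclose(adjusted, [0.02, 0.02, 0.04, 0.04])
        assert reject.all()

    def test_all_ones_rejects_nothing(self):
        adjusted, reject = bh_adjust([1.0] * 6, q=0.05)
        assert not reject.any() and (adjusted == 1).all()

    def test_single_p_is_identity(self):
        adjusted, reject = bh_adjust([0.04], q=0.05)
        assert adjusted[0] == pytest.approx(0.04) and reject[0]

    def test_nan_entries_excluded_from_family_size(self):
        adjusted, reject = bh_adjust([0.01, np.nan, 0.04], q=0.05)
        clean, _ = bh_adjust([0.01, 0.04], q=0.05)
        np.testing.assert_allclose(adjusted[[0, 2]], clean)
        assert np.isnan(adjusted[1]) and not reject[1]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.2], q=0.05)

    def test_matches_exhaustive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            m = rng.integers(1, 13)
            p = np.round(rng.random(m), 3)
            q = rng.choice([0.01, 0.05, 0.1, 0.2])
            adjusted, reject = bh_adjust(p, q)
            o_adj, o_rej = bh_oracle(p, q)
            np.testing.assert_allclose(adjusted, o_adj, atol=1e-12)
            assert (reject == o_rej).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(40)
        adjusted, reject = bh_adjust(p, q=0.05)
        ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adjusted, ref_adj, atol=1e-12)
        assert (reject == ref_rej).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_rejections_monotone_in_q(self, pvals):
        _, r_small = bh_adjust(pvals, q=0.02)
        _, r_large = bh_adjust(pvals, q=0.10)
        assert not (r_small & ~r_large).any()


@pytest.fixture(scope="module")
def demo_screen():
    cfg = default_config()
    cohort, mats, truth = simulate_analysis_frame(cfg, levels=(2, 4))
    sc = ScreenConfig(split_seed=3)
    cohort = split_cohort(cohort, 0.5, 3)
    return cohort, mats, run_two_stage_screen(cohort, mats, sc), sc


class TestFitDrugModel:
    def test_recoding_exposure_inverts_hazard_ratio(self, demo_screen):
        cohort, mats, _, sc = demo_screen
        rows = cohort.loc[cohort["split"] == "discovery"]
        cls = mats[4].frame.reindex(rows["patient_id"])["N07AA"].to_numpy()
        keep = cls != "prevalent_user"
        rows = rows.loc[keep]
        x = (cls[keep] == "incident_user").astype(float)
        a = fit_drug_model(rows, x, "all_cause", sc)
        b = fit_drug_model(rows, 1.0 - x, "all_cause", sc)
        assert a.converged and b.converged
        assert a.log_hr == pytest.approx(-b.log_hr, rel=1e-8, abs=1e-10)
        assert a.p_raw == pytest.approx(b.p_raw, rel=1e-8)

    def test_all_zero_exposure_is_degenerate_not_fatal(self, demo_screen):
        cohort, _, _, sc = demo_screen
        rows = cohort.loc[cohort["split"] == "discovery"]
        res = fit_drug_model(rows, np.zeros(len(rows)), "all_cause", sc)
        assert not res.converged and res.reason == "degenerate exposure"

    def test_result_row_counts_are_bookkept(self, demo_screen):
        cohort, mats, _, sc = demo_screen
        rows = cohort.loc[cohort["split"] == "validation"]
        cls = mats[4].frame.reindex(rows["patient_id"])["B01AC"].to_numpy()
        keep = cls != "prevalent_user"
        x = (cls[keep] == "incident_user").astype(float)
        res = fit_drug_model(rows.loc[keep], x, "cancer_specific", sc)
        assert res.n_users == int(x.sum())
        assert res.n_users + res.n_nonusers == keep.sum()


class TestTwoStageScreen:
    def test_validated_subset_of_discovery(self, demo_screen):
        *_, report, _ = demo_screen
        assert set(report.validated_signals) <= set(report.discovery_signals)

    def test_planted_effects_recovered_in_demo(self, demo_screen):
        *_, report, _ = demo_screen
        validated_drugs = {d for _, _, d in report.validated_signals}
        assert {"N07AA", "A02AA"} <= validated_drugs

    def test_direction_labels_follow_hazard_ratios(self, demo_screen):
        *_, report, _ = demo_screen
        res = report.results
        for (level, outcome, drug), direction in report.directions.items():
            sl = res[(res["level"] == level) & (res["outcome"] == outcome)
                     & (res["drug"] == drug)]
            hrs = sl["hr"].to_numpy()
            if direction == "protective":
                assert (hrs < 1).all()
            elif direction == "detrimental":
                assert (hrs > 1).all()

    def test_patient_order_invariance(self):
        cfg = high_mortality_config(
            500, (DrugSpec("N07AA02", 0.15, 0.05, 0.5, 0.5),), seed=21
        )
        cohort, mats, _ = simulate_analysis_frame(cfg, levels=(4,))
        sc = ScreenConfig(split_seed=2, outcomes=("all_cause",),
                          min_users_per_arm=5)
        a = run_two_stage_screen(split_cohort(cohort, 0.5, 2), mats, sc)
        shuffled = cohort.sample(frac=1, random_state=4).reset_index(drop=True)
        b = run_two_stage_screen(split_cohort(shuffled, 0.5, 2), mats, sc)
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_unsplit_cohort_rejected(self, demo_screen):
        cohort, mats, _, sc = demo_screen
        unsplit = cohort.assign(split="unassigned")
        with pytest.raises(ValidationError, match="split"):
            run_two_stage_screen(unsplit, mats, sc)

    def test_empty_drug_list_warns_and_returns_empty(self, demo_screen):
        cohort, _, _, sc = demo_screen
        from mwascreen.exposure import ExposureMatrix

        empty = ExposureMatrix(
            atc_level=4, drugs=[],
            frame=pd.DataFrame(
                index=pd.Index(cohort["patient_id"], name="patient_id")
            ),
        )
        with pytest.warns(UserWarning, match="no eligible drugs"):
            report = run_two_stage_screen(cohort, {4: empty}, sc)
        assert len(report.results) == 0
        assert report.discovery_signals == []

    def test_validation_rows_only_for_discovery_signals(self, demo_screen):
        *_, report, _ = demo_screen
        val_rows = report.results.loc[report.results["stage"] == "validation"]
        keys = {
            (int(r.level), r.outcome, r.drug)
            for r in val_rows.itertuples(index=False)
        }
        assert keys == set(report.discovery_signals)


class TestScreenConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            ScreenConfig(fdr_q=0.0)
        with pytest.raises(ValidationError):
            ScreenConfig(ties_method="exact")
        with pytest.raises(ValidationError):
            ScreenConfig(adjustment_set=("sex", "income"))

    def test_dict_round_trip(self):
        cfg = ScreenConfig(fdr_q=0.1, split_seed=42, outcomes=("all_cause",))
        assert ScreenConfig.from_dict(cfg.to_dict()) == cfg
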