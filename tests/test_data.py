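"""Day-level preparation: reading, aggregation, eligibility, centering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emalag as em
from emalag.data import EFFORT_ACTIVITIES, _effort_col, _occ_col


def _ema_row(pid="p0", day=0, slot=0, activity="rest", effort=1.0, **scores):
    row = {
        "participant_id": pid, "day_index": day, "slot_index": slot,
        "activity_category": activity, "effort": effort,
    }
    for c in list(em.SYMPTOMS) + list(em.EXPOSURES):
        row[c] = scores.get(c, 2.0)
    return row


def _cov_row(pid="p0", **kw):
    row = {
        "participant_id": pid, "age_years": 48, "sex": "female",
        "minority_ethnicity": 0, "employment": "full-time",
        "setting": "clinic", "autoimmune": 0, "mental_health_condition": 0,
        "asymptomatic_initial": 0, "hospitalized": 0, "icu": 0,
        "variant": "omicron", "vaccinated_before_infection": 1,
        "lc_duration_months": 15,
    }
    row.update(kw)
    return row


def _write(tmp_path, ema_rows, cov_rows):
    ema = tmp_path / "ema.csv"
    cov = tmp_path / "cov.csv"
    pd.DataFrame(ema_rows).to_csv(ema, index=False)
    pd.DataFrame(cov_rows).to_csv(cov, index=False)
    return ema, cov


def _day_frame(pid, day_indices, **overrides):
    """Complete day rows for one participant (all scores present)."""
    rows = []
    for d in day_indices:
        row = {"participant_id": pid, "day_index": d, "n_prompts": 5}
        for c in list(em.SYMPTOMS) + list(em.EXPOSURES):
            row[c] = overrides.get(c, 3.0)
        for a in EFFORT_ACTIVITIES:
            row[_effort_col(a)] = 1.0
            row[_occ_col(a)] = 1
        rows.append(row)
    return pd.DataFrame(rows)


def _dataset(frames):
    days = pd.concat(frames, ignore_index=True)
    covs = pd.DataFrame(
        [_cov_row(pid) for pid in days["participant_id"].unique()]
    ).set_index("participant_id")
    return em.DayLevelDataset(days, covs)


class TestReadEmaLong:
    def test_five_slots_one_day(self, tmp_path):
        rows = [_ema_row(slot=s) for s in range(5)]
        ema, cov = _write(tmp_path, rows, [_cov_row()])
        cohort, report = em.read_ema_long(ema, cov)
        assert report["n_accepted"] == 5 and report["n_rejected"] == 0
        recs = cohort.to_records()
        assert sorted(r.slot_index for r in recs) == [0, 1, 2, 3, 4]
        assert all(r.symptom_scores["fatigue"] == 2.0 for r in recs)

    def test_out_of_range_score_rejected(self, tmp_path):
        rows = [_ema_row(slot=0), _ema_row(slot=1, fatigue=12.0)]
        ema, cov = _write(tmp_path, rows, [_cov_row()])
        cohort, report = em.read_ema_long(ema, cov)
        assert report["n_rejected"] == 1
        assert "fatigue" in report["rejections"][0]
        assert len(cohort.records) == 1

    def test_unknown_activity_rejected(self, tmp_path):
        rows = [_ema_row(slot=0, activity="gardening"), _ema_row(slot=1)]
        ema, cov = _write(tmp_path, rows, [_cov_row()])
        _, report = em.read_ema_long(ema, cov)
        assert report["n_rejected"] == 1

    def test_duplicate_slot_rejected(self, tmp_path):
        rows = [_ema_row(slot=0), _ema_row(slot=0)]
        ema, cov = _write(tmp_path, rows, [_cov_row()])
        _, report = em.read_ema_long(ema, cov)
        assert report["n_accepted"] == 1

    def test_conflicting_covariates_hard_error(self, tmp_path):
        rows = [_ema_row()]
        covs = [_cov_row(), _cov_row(age_years=60)]
        ema, cov = _write(tmp_path, rows, covs)
        with pytest.raises(ValueError, match="conflicting"):
            em.read_ema_long(ema, cov)

    def test_employment_collapsed_to_three_levels(self, tmp_path):
        rows = [_ema_row()]
        ema, cov = _write(tmp_path, rows,
                          [_cov_row(employment="not in paid employment")])
        cohort, _ = em.read_ema_long(ema, cov)
        assert cohort.covariates.loc["p0", "employment"] == "other"

    def test_schema_remapping(self, tmp_path):
        rows = [_ema_row()]
        df = pd.DataFrame(rows).rename(columns={"participant_id": "subj"})
        ema = tmp_path / "e.csv"
        df.to_csv(ema, index=False)
        cohort, _ = em.read_ema_long(ema, schema={"participant_id": "subj"})
        assert list(cohort.records["participant_id"]) == ["p0"]


class TestAggregateToDays:
    def test_constant_slots(self):
        rows = [_ema_row(slot=s, fatigue=4.0) for s in range(5)]
        ds = em.aggregate_to_days(em.Cohort(pd.DataFrame(rows), pd.DataFrame()))
        assert ds.days.loc[0, "fatigue"] == 4.0

    def test_mean_of_available_values(self):
        vals = [2.0, 4.0, np.nan, 6.0, 8.0]
        rows = [_ema_row(slot=s, fatigue=v) for s, v in enumerate(vals)]
        ds = em.aggregate_to_days(em.Cohort(pd.DataFrame(rows), pd.DataFrame()))
        assert ds.days.loc[0, "fatigue"] == pytest.approx(5.0)

    def test_all_slots_missing_gives_missing_day(self):
        rows = [_ema_row(slot=s, stress=np.nan) for s in range(5)]
        ds = em.aggregate_to_days(em.Cohort(pd.DataFrame(rows), pd.DataFrame()))
        assert np.isnan(ds.days.loc[0, "stress"])

    def test_effort_mean_per_activity_and_occurrence(self):
        rows = [
            _ema_row(slot=0, activity="physical", effort=4.0),
            _ema_row(slot=1, activity="physical", effort=6.0),
            _ema_row(slot=2, activity="rest", effort=0.0),
        ]
        ds = em.aggregate_to_days(em.Cohort(pd.DataFrame(rows), pd.DataFrame()))
        day = ds.days.iloc[0]
        assert day[_effort_col("physical")] == pytest.approx(5.0)
        assert day[_occ_col("physical")] == 1
        assert day[_effort_col("social")] == 0.0
        assert day[_occ_col("social")] == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(
        st.one_of(st.none(), st.floats(0, 10, allow_nan=False)),
        min_size=1, max_size=5,
    ).filter(lambda vs: any(v is not None for v in vs)))
    def test_day_value_within_slot_range(self, values):
        rows = [_ema_row(slot=s, pain=(np.nan if v is None else v))
                for s, v in enumerate(values)]
        ds = em.aggregate_to_days(em.Cohort(pd.DataFrame(rows), pd.DataFrame()))
        present = [v for v in values if v is not None]
        day = ds.days.loc[0, "pain"]
        assert min(present) - 1e-12 <= day <= max(present) + 1e-12


class TestFilterConsecutiveRuns:
    def test_six_days_excluded(self):
        ds = _dataset([_day_frame("p0", range(6))])
        out = em.filter_consecutive_runs(ds)
        assert len(out.days) == 0
        assert "excluded" in out.exclusion_report

    def test_gap_splits_runs_and_short_run_dropped(self):
        ds = _dataset([_day_frame("p0", [0, 1, 2, 3, 4, 6, 7, 8, 9, 10, 11, 12, 13])])
        out = em.filter_consecutive_runs(ds)
        assert sorted(out.days["day_index"]) == list(range(6, 14))
        assert out.days["run_id"].nunique() == 1

    def test_exact_boundary_seven_days_retained(self):
        ds = _dataset([_day_frame("p0", range(7))])
        out = em.filter_consecutive_runs(ds)
        assert len(out.days) == 7
        assert out.days["run_id"].nunique() == 1

    def test_missing_exposure_day_breaks_run(self):
        good = _day_frame("p0", range(15))
        good.loc[good["day_index"] == 7, "stress"] = np.nan
        out = em.filter_consecutive_runs(_dataset([good]))
        # days 0-6 and 8-14 both qualify as 7-day runs
        assert out.days["run_id"].nunique() == 2
        assert 7 not in set(out.days["day_index"])

    def test_idempotent(self):
        ds = _dataset([
            _day_frame("p0", range(9)),
            _day_frame("p1", range(4)),
        ])
        once = em.filter_consecutive_runs(ds)
        twice = em.filter_consecutive_runs(once)
        pd.testing.assert_frame_equal(
            once.days.reset_index(drop=True), twice.days.reset_index(drop=True)
        )

    def test_min_days_below_three_rejected(self):
        ds = _dataset([_day_frame("p0", range(9))])
        with pytest.raises(ValueError, match="lag-2"):
            em.filter_consecutive_runs(ds, min_days=2)

    def test_participant_with_no_run_dropped_from_covariates(self):
        ds = _dataset([
            _day_frame("p0", range(8)),
            _day_frame("p1", range(3)),
        ])
        out = em.filter_consecutive_runs(ds)
        assert list(out.covariates.index) == ["p0"]


class TestGrandMeanCenter:
    def test_basic_centering(self):
        ds = _dataset([_day_frame("p0", range(7))])
        ds.days.loc[:, "stress"] = np.arange(7.0)  # mean 3
        out, consts = em.grand_mean_center(ds, ["stress"])
        assert consts["stress"] == pytest.approx(3.0)
        assert np.allclose(out.days["stress"], np.arange(7.0) - 3.0)

    def test_centering_twice_is_noop(self):
        ds = _dataset([_day_frame("p0", range(7))])
        ds.days.loc[:, "stress"] = [1.0, 2, 3, 4, 5, 6, 7]
        once, _ = em.grand_mean_center(ds, ["stress"])
        twice, consts2 = em.grand_mean_center(once, ["stress"])
        assert abs(consts2["stress"]) < 1e-12
        assert np.allclose(once.days["stress"], twice.days["stress"])
        # accumulated constant still maps back to the raw scale
        assert twice.centering["stress"] == pytest.approx(4.0)

    def test_categorical_rejected(self):
        ds = _dataset([_day_frame("p0", range(7))])
        with pytest.raises(ValueError, match="categorical"):
            em.grand_mean_center(ds, ["sex"])

    def test_participant_level_variable_centered_over_participants(self):
        ds = _dataset([_day_frame("p0", range(7)), _day_frame("p1", range(10))])
        ds.covariates.loc["p0", "age_years"] = 40.0
        ds.covariates.loc["p1", "age_years"] = 60.0
        out, consts = em.grand_mean_center(ds, ["age_years"])
        # mean over participants (50), not day rows (weighted 51.76)
        assert consts["age_years"] == pytest.approx(50.0)

    def test_simulated_cohort_centered_mean_is_zero(self):
        cohort = em.simulate_cohort(em.SimConfig(n_participants=12, seed=5))
        days = em.filter_consecutive_runs(em.aggregate_to_days(cohort))
        out, _ = em.grand_mean_center(days, ["stress"])
        assert abs(out.days["stress"].mean()) < 1e-12


class TestRoundTrip:
    def test_write_read_preserves_numeric_fields(self, tmp_path):
        cohort = em.simulate_cohort(em.SimConfig(n_participants=8, seed=9))
        days = em.filter_consecutive_runs(em.aggregate_to_days(cohort))
        days, _ = em.grand_mean_center(days, ["stress", "worry"])
        days.write(tmp_path / "out")
        back = em.DayLevelDataset.read(tmp_path / "out")
        num = days.days.select_dtypes("number")
        pd.testing.assert_frame_equal(
            num.reset_index(drop=True),
            back.days[num.columns].reset_index(drop=True),
            check_exact=True,
        )
        assert back.centering == days.centering

    def test_total_day_count_matches_per_participant_sum(self):
        cohort = em.simulate_cohort(em.SimConfig(n_participants=10, seed=3))
        days = em.filter_consecutive_runs(em.aggregate_to_days(cohort))
        per_part = days.days.groupby("participant_id").size()
        assert per_part.sum() == len(days.days)
        first = days.exclusion_report.splitlines()[0]
        assert f"retained {len(days.days)} day(s)" in first
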