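"""Core data types and day-level preparation for intensive-longitudinal EMA data.

The raw unit of observation is one smartphone prompt: five per day at
3-hourly slots (09:00–21:00), each carrying 0–10 severity scores for eight
Long COVID symptoms, 0–10 scores for three perseverative-cognition exposures
(stress, worry, rumination), and the primary activity with its effort.

Analysis happens at day level: prompt scores are collapsed to daily means,
days are partitioned into maximal runs of consecutive complete days, runs
shorter than a minimum length (default 7 days) are dropped, and continuous
variables are grand-mean-centered so model coefficients are interpreted
relative to the cohort average.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SYMPTOMS",
    "EXPOSURES",
    "EFFORT_ACTIVITIES",
    "ACTIVITY_CATEGORIES",
    "EMARecord",
    "ParticipantCovariates",
    "Cohort",
    "DayLevelDataset",
    "read_ema_long",
    "aggregate_to_days",
    "filter_consecutive_runs",
    "grand_mean_center",
]

SYMPTOMS: tuple[str, ...] = (
    "breathlessness",
    "fatigue",
    "pain",
    "dizziness",
    "palpitations",
    "anxiety",
    "depression",
    "cognitive_dysfunction",
)
EXPOSURES: tuple[str, ...] = ("stress", "worry", "rumination")
#: activity categories whose mean daily effort enters the model as a confounder
EFFORT_ACTIVITIES: tuple[str, ...] = ("physical", "cognitive", "social", "self-care")
ACTIVITY_CATEGORIES: tuple[str, ...] = EFFORT_ACTIVITIES + ("rest", "sleep")

SEX_LEVELS = ("female", "male")
EMPLOYMENT_LEVELS = ("full-time", "part-time", "other")
SETTING_LEVELS = ("clinic", "community")
VARIANT_LEVELS = ("original", "alpha", "delta", "omicron")

#: raw employment labels collapsed into the model's three-level adjustment set
_EMPLOYMENT_COLLAPSE = {
    "full-time": "full-time",
    "part-time": "part-time",
    "self-employed": "other",
    "not in paid employment": "other",
    "unemployed": "other",
    "retired": "other",
    "other": "other",
}

_FLAG_FIELDS = (
    "minority_ethnicity",
    "autoimmune",
    "mental_health_condition",
    "asymptomatic_initial",
    "hospitalized",
    "icu",
    "vaccinated_before_infection",
)
_TRUE_STRINGS = {"1", "true", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "no", "n"}


def _effort_col(activity: str) -> str:
    return "effort_" + activity.replace("-", "_")


def _occ_col(activity: str) -> str:
    return "occ_" + activity.replace("-", "_")


EFFORT_COLUMNS = tuple(_effort_col(a) for a in EFFORT_ACTIVITIES)
OCCURRENCE_COLUMNS = tuple(_occ_col(a) for a in EFFORT_ACTIVITIES)


@dataclass(frozen=True)
class EMARecord:
    """One prompt-level observation.

    ``slot_index`` is the ordinal position of the prompt within the day
    (0 → 09:00 … 4 → 21:00); clock times themselves are not modelled.
    Missing scores are ``None``.
    """

    participant_id: str
    day_index: int
    slot_index: int
    activity_category: str | None
    effort: float | None
    symptom_scores: Mapping[str, float | None]
    exposure_scores: Mapping[str, float | None]

    def __post_init__(self) -> None:
        if not 0 <= self.slot_index <= 4:
            raise ValueError("slot_index must be in 0..4")
        if self.day_index < 0:
            raise ValueError("day_index must be >= 0")
        for name, score in {
            **dict(self.symptom_scores),
            **dict(self.exposure_scores),
            "effort": self.effort,
        }.items():
            if score is not None and not 0.0 <= score <= 10.0:
                raise ValueError(f"{name} score {score} outside [0, 10]")


@dataclass(frozen=True)
class ParticipantCovariates:
    """Participant-level adjustment variables."""

    participant_id: str
    age_years: float
    sex: str
    minority_ethnicity: bool
    employment: str
    setting: str
    autoimmune: bool
    mental_health_condition: bool
    asymptomatic_initial: bool
    hospitalized: bool
    icu: bool
    variant: str
    vaccinated_before_infection: bool
    lc_duration_months: float

    def __post_init__(self) -> None:
        if self.age_years < 18:
            raise ValueError("participants are adults; age must be >= 18")
        for name, value, levels in (
            ("sex", self.sex, SEX_LEVELS),
            ("employment", self.employment, EMPLOYMENT_LEVELS),
            ("setting", self.setting, SETTING_LEVELS),
            ("variant", self.variant, VARIANT_LEVELS),
        ):
            if value not in levels:
                raise ValueError(f"{name}={value!r} not in {levels}")


@dataclass
class Cohort:
    """Prompt-level records plus one covariate row per participant.

    ``records`` is long-format: one row per (participant, day, slot) with
    the symptom/exposure score columns, ``activity_category`` and
    ``effort``.  ``covariates`` is indexed by ``participant_id``.
    """

    records: pd.DataFrame
    covariates: pd.DataFrame

    def to_records(self) -> list[EMARecord]:
        out = []
        for row in self.records.itertuples(index=False):
            d = row._asdict()
            out.append(
                EMARecord(
                    participant_id=str(d["participant_id"]),
                    day_index=int(d["day_index"]),
                    slot_index=int(d["slot_index"]),
                    activity_category=(
                        None if pd.isna(d["activity_category"]) else d["activity_category"]
                    ),
                    effort=None if pd.isna(d["effort"]) else float(d["effort"]),
                    symptom_scores={
                        s: (None if pd.isna(d[s]) else float(d[s])) for s in SYMPTOMS
                    },
                    exposure_scores={
                        e: (None if pd.isna(d[e]) else float(d[e])) for e in EXPOSURES
                    },
                )
            )
        return out

    def to_covariate_objects(self) -> list[ParticipantCovariates]:
        fields = [f.name for f in dataclasses.fields(ParticipantCovariates)]
        out = []
        for pid, row in self.covariates.iterrows():
            kwargs = {"participant_id": str(pid)}
            for f in fields[1:]:
                v = row[f]
                kwargs[f] = bool(v) if f in _FLAG_FIELDS else v
            out.append(ParticipantCovariates(**kwargs))
        return out


@dataclass
class DayLevelDataset:
    """Day-aggregated scores with run structure and centering bookkeeping.

    ``days`` has one row per (participant, day): daily means of the eight
    symptoms and three exposures, per-activity mean efforts (0 when the
    activity did not occur, with an occurrence indicator alongside), and,
    after :func:`filter_consecutive_runs`, a ``run_id`` labelling the
    maximal consecutive-day run the day belongs to.  ``centering`` maps a
    variable name to the grand mean subtracted from it, so effects can be
    reported back on the raw 0–10 scale.
    """

    days: pd.DataFrame
    covariates: pd.DataFrame
    centering: dict[str, float] = field(default_factory=dict)
    exclusion_report: str = ""

    DAY_KEY = ["participant_id", "day_index"]

    def copy(self) -> "DayLevelDataset":
        return DayLevelDataset(
            self.days.copy(), self.covariates.copy(), dict(self.centering),
            self.exclusion_report,
        )

    # -- persistence ------------------------------------------------------
    def write(self, out_dir: str | Path) -> None:
        """Write day-level CSV, covariates CSV, centering constants and the
        exclusion report under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.days.to_csv(out / "days.csv", index=False, float_format="%.17g")
        self.covariates.to_csv(out / "covariates.csv", float_format="%.17g")
        pd.Series(self.centering, name="grand_mean", dtype=float).rename_axis(
            "variable"
        ).to_csv(out / "centering.csv")
        (out / "exclusions.txt").write_text(self.exclusion_report)

    @classmethod
    def read(cls, in_dir: str | Path) -> "DayLevelDataset":
        out = Path(in_dir)
        days = pd.read_csv(out / "days.csv", float_precision="round_trip")
        covs = pd.read_csv(out / "covariates.csv", index_col="participant_id",
                           float_precision="round_trip")
        covs.index = covs.index.astype(str)
        days["participant_id"] = days["participant_id"].astype(str)
        cent_path = out / "centering.csv"
        centering: dict[str, float] = {}
        if cent_path.exists():
            cent = pd.read_csv(cent_path, float_precision="round_trip")
            if len(cent):
                centering = dict(zip(cent["variable"], cent["grand_mean"].astype(float)))
        report = (out / "exclusions.txt")
        return cls(
            days, covs, centering,
            report.read_text() if report.exists() else "",
        )


# ---------------------------------------------------------------------------
# reading long-format CSV


def _parse_flag(value, row_errors: list[str], name: str) -> bool | None:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    row_errors.append(f"unparseable flag {name}={value!r}")
    return None


def read_ema_long(
    ema_path: str | Path,
    covariates_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
) -> tuple[Cohort, dict]:
    """Read a long-format prompt-level CSV (and covariate CSV) into a Cohort.

    ``schema`` maps canonical column names to the file's column names for
    files with different headers.  Rows with scores outside [0, 10], unknown
    categorical levels, or duplicated (participant, day, slot) keys are
    rejected with a logged reason; conflicting covariate rows for one
    participant are a hard error.  Returns the cohort plus a report dict
    with ``n_rows``, ``n_accepted``, ``n_rejected`` and ``rejections``.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(ema_path, dtype={schema.get("participant_id", "participant_id"): str})
    colmap = {schema.get(c, c): c for c in (
        ["participant_id", "day_index", "slot_index", "activity_category", "effort"]
        + list(SYMPTOMS) + list(EXPOSURES)
    )}
    missing_cols = [src for src in colmap if src not in raw.columns]
    if missing_cols:
        raise ValueError(f"EMA file missing columns: {missing_cols}")
    raw = raw.rename(columns=colmap)

    rejections: list[str] = []
    keep = np.ones(len(raw), dtype=bool)
    score_cols = list(SYMPTOMS) + list(EXPOSURES) + ["effort"]
    for i, row in raw.iterrows():
        reasons = []
        for c in score_cols:
            v = row[c]
            if pd.notna(v) and not (0.0 <= float(v) <= 10.0):
                reasons.append(f"{c}={v} outside [0,10]")
        act = row["activity_category"]
        if pd.notna(act) and act not in ACTIVITY_CATEGORIES:
            reasons.append(f"unknown activity_category {act!r}")
        if not (0 <= int(row["slot_index"]) <= 4):
            reasons.append(f"slot_index {row['slot_index']} outside 0..4")
        if reasons:
            keep[i] = False
            rejections.append(f"row {i}: " + "; ".join(reasons))
    records = raw.loc[keep].copy()

    dup = records.duplicated(["participant_id", "day_index", "slot_index"], keep="first")
    for i in records.index[dup]:
        rejections.append(f"row {i}: duplicate (participant, day, slot)")
    records = records.loc[~dup]

    if covariates_path is not None:
        covariates = _read_covariates(covariates_path)
    else:
        covariates = pd.DataFrame(index=pd.Index(records["participant_id"].unique(),
                                                 name="participant_id"))
    report = {
        "n_rows": int(len(raw)),
        "n_accepted": int(len(records)),
        "n_rejected": int(len(raw) - len(records)),
        "rejections": rejections,
    }
    return Cohort(records.reset_index(drop=True), covariates), report


def _read_covariates(path: str | Path) -> pd.DataFrame:
    covs = pd.read_csv(path, dtype={"participant_id": str})
    if covs["participant_id"].duplicated().any():
        dups = covs[covs["participant_id"].duplicated(keep=False)]
        # duplicates are allowed only if fully consistent
        if dups.groupby("participant_id").nunique().to_numpy().max() > 1:
            raise ValueError("conflicting covariate rows for a participant")
        covs = covs.drop_duplicates("participant_id")
    covs = covs.set_index("participant_id")
    errors: list[str] = []
    covs["employment"] = covs["employment"].map(
        lambda v: _EMPLOYMENT_COLLAPSE.get(str(v).strip().lower())
    )
    if covs["employment"].isna().any():
        raise ValueError("unknown employment level in covariates")
    for name, levels in (("sex", SEX_LEVELS), ("setting", SETTING_LEVELS),
                         ("variant", VARIANT_LEVELS)):
        bad = ~covs[name].isin(levels)
        if bad.any():
            raise ValueError(f"unknown {name} level(s): {covs.loc[bad, name].unique()}")
    for f in _FLAG_FIELDS:
        covs[f] = [ _parse_flag(v, errors, f) for v in covs[f] ]
    if errors:
        raise ValueError("covariate parse errors: " + "; ".join(errors))
    covs["age_years"] = covs["age_years"].astype(float)
    covs["lc_duration_months"] = covs["lc_duration_months"].astype(float)
    if (covs["age_years"] < 18).any():
        raise ValueError("age must be >= 18")
    return covs


# ---------------------------------------------------------------------------
# day-level aggregation


def aggregate_to_days(cohort: Cohort | Iterable[EMARecord]) -> DayLevelDataset:
    """Collapse prompt-level records to daily means.

    A day's value for a symptom or exposure is the arithmetic mean of its
    non-missing slot scores, and is missing only when all slots are missing.
    Per-activity daily effort is the mean effort over the slots reporting
    that activity, 0 (with occurrence indicator 0) on days the activity
    never occurred.
    """
    if not isinstance(cohort, Cohort):
        cohort = _cohort_from_records(list(cohort))
    rec = cohort.records
    if rec.empty:
        raise ValueError("no records to aggregate")
    key = DayLevelDataset.DAY_KEY
    score_cols = list(SYMPTOMS) + list(EXPOSURES)
    days = rec.groupby(key, sort=True)[score_cols].mean().reset_index()
    days["n_prompts"] = (
        rec.groupby(key, sort=True).size().to_numpy()
    )

    # per-activity effort means over the slots reporting that activity
    for act in EFFORT_ACTIVITIES:
        sub = rec[rec["activity_category"] == act]
        eff = sub.groupby(key)["effort"].mean()
        occ = sub.groupby(key).size()
        days[_effort_col(act)] = (
            days.set_index(key).index.map(eff).to_numpy()
        )
        days[_occ_col(act)] = (
            days.set_index(key).index.map(occ).fillna(0).to_numpy() > 0
        ).astype(int)
        days[_effort_col(act)] = days[_effort_col(act)].fillna(0.0)
    return DayLevelDataset(days, cohort.covariates.copy())


def _cohort_from_records(records: list[EMARecord]) -> Cohort:
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "day_index": r.day_index,
            "slot_index": r.slot_index,
            "activity_category": r.activity_category,
            "effort": r.effort,
        }
        row.update({s: r.symptom_scores.get(s) for s in SYMPTOMS})
        row.update({e: r.exposure_scores.get(e) for e in EXPOSURES})
        rows.append(row)
    frame = pd.DataFrame(rows)
    covs = pd.DataFrame(index=pd.Index(frame["participant_id"].unique(),
                                       name="participant_id"))
    return Cohort(frame, covs)


# ---------------------------------------------------------------------------
# eligibility filter


def filter_consecutive_runs(
    dataset: DayLevelDataset, min_days: int = 7
) -> DayLevelDataset:
    """Keep only maximal runs of >= ``min_days`` consecutive complete days.

    A day is *complete* when every symptom and every exposure has a daily
    value; incomplete days break runs, mirroring the eligibility rule that
    participants need at least ``min_days`` consecutive days of stress /
    worry / rumination reporting.  All qualifying runs of a participant are
    retained (assessment blocks weeks apart yield several); participants
    with no qualifying run are dropped.  Idempotent.
    """
    if min_days < 3:
        raise ValueError(
            "min_days < 3 leaves the lag-2 model unidentifiable (2 conditioning "
            "days + at least 1 likelihood day are needed)"
        )
    days = dataset.days
    complete = days[list(SYMPTOMS) + list(EXPOSURES)].notna().all(axis=1)
    report_lines = []
    kept_parts: list[pd.DataFrame] = []
    n_run = 0
    dropped_participants = []
    for pid, grp in days[complete].groupby("participant_id", sort=True):
        grp = grp.sort_values("day_index")
        d = grp["day_index"].to_numpy()
        breaks = np.flatnonzero(np.diff(d) != 1)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(d) - 1]
        kept_any = False
        for s, e in zip(starts, ends):
            length = e - s + 1
            if length >= min_days:
                run = grp.iloc[s : e + 1].copy()
                run["run_id"] = f"{pid}#r{n_run}"
                n_run += 1
                kept_parts.append(run)
                kept_any = True
            else:
                report_lines.append(
                    f"{pid}: dropped run days {d[s]}..{d[e]} (length {length} < {min_days})"
                )
        if not kept_any:
            dropped_participants.append(pid)

    incomplete_ids = days.loc[~complete, "participant_id"].unique()
    for pid in incomplete_ids:
        n_bad = int(((days["participant_id"] == pid) & ~complete).sum())
        report_lines.append(f"{pid}: {n_bad} incomplete day(s) excluded from runs")
    all_ids = set(days["participant_id"])
    kept = pd.concat(kept_parts, ignore_index=True) if kept_parts else days.iloc[0:0].assign(run_id=[])
    kept_ids = set(kept["participant_id"]) if len(kept) else set()
    for pid in sorted(all_ids - kept_ids):
        report_lines.append(f"{pid}: excluded (no run of >= {min_days} consecutive days)")

    report = "\n".join(
        [f"retained {len(kept)} day(s) in {kept['run_id'].nunique() if len(kept) else 0} "
         f"run(s) across {len(kept_ids)} participant(s); "
         f"excluded {len(all_ids) - len(kept_ids)} participant(s)"]
        + report_lines
    )
    covs = dataset.covariates.loc[dataset.covariates.index.isin(kept_ids)].copy()
    return DayLevelDataset(kept, covs, dict(dataset.centering), report)


# ---------------------------------------------------------------------------
# grand-mean centering


#: variables living at participant level: centered over participants, not days
PARTICIPANT_LEVEL_CONTINUOUS = ("age_years", "lc_duration_months")

_CATEGORICAL_COLUMNS = {
    "sex", "employment", "setting", "variant", "activity_category",
    "participant_id", "run_id",
} | set(_FLAG_FIELDS) | set(OCCURRENCE_COLUMNS)


def grand_mean_center(
    dataset: DayLevelDataset, variables: Iterable[str]
) -> tuple[DayLevelDataset, dict[str, float]]:
    """Subtract the grand mean from each named continuous variable.

    Day-varying variables are centered on the mean over all retained day
    rows; participant-level variables on the mean over participants.  The
    constants are returned (and accumulated on the dataset) so effect
    curves can be mapped back to the raw 0–10 scale.
    """
    ds = dataset.copy()
    constants: dict[str, float] = {}
    for var in variables:
        if var in _CATEGORICAL_COLUMNS:
            raise ValueError(f"cannot grand-mean-center categorical variable {var!r}")
        if var in ds.days.columns:
            mean = float(ds.days[var].mean())
            ds.days[var] = ds.days[var] - mean
        elif var in ds.covariates.columns:
            mean = float(ds.covariates[var].mean())
            ds.covariates[var] = ds.covariates[var] - mean
        else:
            raise KeyError(f"variable {var!r} not found in day or covariate table")
        constants[var] = mean
        ds.centering[var] = ds.centering.get(var, 0.0) + mean
    return ds, constants
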