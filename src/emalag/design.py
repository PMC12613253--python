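"""Model specification and lag-aligned design construction.

The analysis model regresses the 8-vector of daily symptom severities on:

* the previous day's (grand-mean-centered) symptom value — an AR(1)
  transition term with per-symptom coefficient ``rho_k``;
* restricted-cubic-spline expansions of each exposure (stress, worry,
  rumination) on the same day and at lags 1 and 2 — the distributed-lag
  ("AR2") exposure structure;
* mean daily efforts in physical / cognitive / social / self-care
  activities at lags 0–2;
* the participant-level adjustment covariates;
* optionally, interactions of a binary effect modifier with every
  exposure-spline column (for subgroup analyses);

with a participant × symptom random intercept and an unstructured 8×8
residual covariance tying the symptoms together within a day.

Each maximal run of consecutive days contributes likelihood rows only from
its third day onwards; the first two days are conditioning history, so lags
never cross run boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    EFFORT_ACTIVITIES,
    EXPOSURES,
    SYMPTOMS,
    DayLevelDataset,
    _effort_col,
)
from .splines import SplineSpec, rcs_basis

__all__ = ["PriorSpec", "ModelSpec", "DesignMatrices", "build_design"]

#: categorical covariates and their non-reference levels, in design order
_CATEGORICAL_DUMMIES = {
    "sex": [("male", lambda c: c["sex"] == "male")],
    "employment": [
        ("part-time", lambda c: c["employment"] == "part-time"),
        ("other", lambda c: c["employment"] == "other"),
    ],
    "setting": [("community", lambda c: c["setting"] == "community")],
    "variant": [
        ("alpha", lambda c: c["variant"] == "alpha"),
        ("delta", lambda c: c["variant"] == "delta"),
        ("omicron", lambda c: c["variant"] == "omicron"),
    ],
}
_FLAG_COVARIATES = (
    "minority_ethnicity",
    "autoimmune",
    "mental_health_condition",
    "asymptomatic_initial",
    "hospitalized",
    "icu",
    "vaccinated_before_infection",
)
_CONTINUOUS_COVARIATES = ("age_years", "lc_duration_months")

DEFAULT_COVARIATES: tuple[str, ...] = (
    "age_years",
    "sex",
    "minority_ethnicity",
    "employment",
    "setting",
    "autoimmune",
    "mental_health_condition",
    "asymptomatic_initial",
    "hospitalized",
    "icu",
    "variant",
    "vaccinated_before_infection",
    "lc_duration_months",
)

MODIFIERS = ("sex", "mental_health_condition")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the Gibbs sampler; all weakly informative on the 0–10 scale.

    Regression coefficients get zero-mean normals (sd 10); the intercept is
    normal(5, 10) centred mid-scale; random-intercept sds are half-normal(5);
    the residual covariance is inverse-Wishart with ``K + 2`` degrees of
    freedom and identity scale; AR coefficients are uniform on (−1, 1).
    """

    coef_sd: float = 10.0
    intercept_mean: float = 5.0
    intercept_sd: float = 10.0
    tau_scale: float = 5.0
    sigma_extra_df: float = 2.0  # df = n_symptoms + sigma_extra_df
    sigma_scale: float = 1.0     # multiplies the identity scale matrix

    def __post_init__(self) -> None:
        for name in ("coef_sd", "intercept_sd", "tau_scale", "sigma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model fit."""

    symptoms: tuple[str, ...] = SYMPTOMS
    exposures: tuple[str, ...] = EXPOSURES
    lags: tuple[int, ...] = (0, 1, 2)
    spline: SplineSpec | dict[str, SplineSpec] = field(default_factory=SplineSpec)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    activity_lags: tuple[int, ...] = (0, 1, 2)
    interaction: str | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    impute_missing: bool = False
    ar1: bool = True                 # lagged-response transition term
    random_intercepts: bool = True   # participant x symptom intercepts

    def __post_init__(self) -> None:
        if not set(self.lags) <= {0, 1, 2}:
            raise ValueError("lags must be a subset of {0, 1, 2}")
        if not self.lags:
            raise ValueError("at least one exposure lag is required")
        if self.interaction is not None and self.interaction not in MODIFIERS:
            raise ValueError(f"interaction must be one of {MODIFIERS}")
        unknown = set(self.covariates) - set(DEFAULT_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")

    def spline_for(self, exposure: str) -> SplineSpec:
        if isinstance(self.spline, dict):
            return self.spline[exposure]
        return self.spline


@dataclass
class DesignMatrices:
    """Numeric realization of a :class:`ModelSpec` on a day-level dataset.

    ``X`` holds every fixed-effect predictor shared across symptoms (the
    AR term is symptom-specific and lives in ``Ylag``).  ``col_blocks``
    records, for every (exposure, lag), which columns are the linear /
    nonlinear spline components and which are their modifier interactions —
    the joint tests operate on those index sets.
    """

    Y: np.ndarray                      # (n, K) responses
    Ylag: np.ndarray                   # (n, K) centered lag-1 responses
    X: np.ndarray                      # (n, p)
    col_names: list[str]
    participant_index: np.ndarray      # (n,) codes into participant_ids
    participant_ids: list[str]
    row_meta: pd.DataFrame             # participant_id, day_index, run_id
    spec: ModelSpec
    knots: dict[str, np.ndarray]
    exposure_means: dict[str, float]
    exposure_p99: dict[str, float]
    symptom_grand_means: np.ndarray    # (K,)
    col_blocks: dict[tuple[str, int], dict[str, list[int]]]
    Ymask: np.ndarray                  # (n, K) True where observed
    prev_row: np.ndarray               # (n,) row index of day t-1, or -1

    @property
    def n_rows(self) -> int:
        return self.Y.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.Y.shape[1]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def manifest(self) -> dict:
        """Serializable description of the design for reproducibility."""
        return {
            "columns": list(self.col_names),
            "symptoms": list(self.spec.symptoms),
            "exposures": list(self.spec.exposures),
            "lags": list(self.spec.lags),
            "knots": {e: list(map(float, k)) for e, k in self.knots.items()},
            "exposure_means": {e: float(v) for e, v in self.exposure_means.items()},
            "exposure_p99": {e: float(v) for e, v in self.exposure_p99.items()},
            "symptom_grand_means": list(map(float, self.symptom_grand_means)),
            "interaction": self.spec.interaction,
            "col_blocks": {
                f"{e}:lag{l}": blocks for (e, l), blocks in self.col_blocks.items()
            },
        }


def _covariate_columns(spec: ModelSpec, covs: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Expand the adjustment set into named numeric columns (one row per
    participant, ordered like ``covs.index``)."""
    names: list[str] = []
    cols: list[np.ndarray] = []
    for cov in spec.covariates:
        if cov not in covs.columns:
            raise ValueError(f"covariate {cov!r} missing from covariate table")
        if cov in _CATEGORICAL_DUMMIES:
            for level, fn in _CATEGORICAL_DUMMIES[cov]:
                names.append(f"{cov}[{level}]")
                cols.append(fn(covs).to_numpy(dtype=float))
        elif cov in _FLAG_COVARIATES:
            names.append(cov)
            cols.append(covs[cov].to_numpy(dtype=float))
        else:  # continuous: grand-mean-center over participants
            v = covs[cov].to_numpy(dtype=float)
            names.append(cov)
            cols.append(v - v.mean())
    mat = np.column_stack(cols) if cols else np.empty((len(covs), 0))
    return names, mat


def _modifier_indicator(spec: ModelSpec, covs: pd.DataFrame) -> np.ndarray:
    if spec.interaction == "sex":
        return (covs["sex"] == "male").to_numpy(dtype=float)
    return covs[spec.interaction].to_numpy(dtype=float)


def build_design(dataset: DayLevelDataset, spec: ModelSpec) -> DesignMatrices:
    """Construct lag-aligned design matrices from a filtered day-level dataset.

    Likelihood rows exist only for days whose run contains both required
    lags; exposures are expanded through the restricted-cubic-spline basis
    evaluated on the raw 0–10 scale and referenced to the exposure's grand
    mean, so the intercept is interpretable as expected severity at average
    exposure.
    """
    days = dataset.days
    if "run_id" not in days.columns or days["run_id"].isna().any():
        raise ValueError("dataset must pass filter_consecutive_runs first")
    max_lag = max(max(spec.lags), max(spec.activity_lags, default=0), 1)
    run_lengths = days.groupby("run_id").size()
    if (run_lengths <= max_lag).any():
        raise ValueError("a run is too short for the requested lags")

    # undo any recorded centering so knots sit on the raw 0-10 scale
    raw = days.copy()
    for v, c in dataset.centering.items():
        if v in raw.columns:
            raw[v] = raw[v] + c

    exposure_means = {e: float(raw[e].mean()) for e in spec.exposures}
    exposure_p99 = {e: float(np.quantile(raw[e], 0.99)) for e in spec.exposures}
    knots = {
        e: spec.spline_for(e).resolve_knots(raw[e].to_numpy())
        for e in spec.exposures
    }
    symptom_means = raw[list(spec.symptoms)].mean().to_numpy()

    effort_cols = [_effort_col(a) for a in EFFORT_ACTIVITIES]
    effort_means = {c: float(raw[c].mean()) for c in effort_cols}

    covs = dataset.covariates.loc[
        sorted(days["participant_id"].unique())
    ]
    cov_names, cov_mat = _covariate_columns(spec, covs)
    participant_ids = list(covs.index.astype(str))
    pid_code = {p: i for i, p in enumerate(participant_ids)}
    if spec.interaction is not None:
        modifier = _modifier_indicator(spec, covs)

    rows_Y, rows_Ylag, rows_meta = [], [], []
    spline_parts: dict[tuple[str, int], list[np.ndarray]] = {
        (e, l): [] for e in spec.exposures for l in spec.lags
    }
    effort_parts: dict[tuple[str, int], list[np.ndarray]] = {
        (c, l): [] for c in effort_cols for l in spec.activity_lags
    }
    part_codes: list[int] = []
    prev_rows: list[int] = []
    row_counter = 0
    row_of: dict[tuple[str, int], int] = {}

    n_cond = 2  # conditioning days at the start of each run
    for run_id, grp in raw.groupby("run_id", sort=True):
        grp = grp.sort_values("day_index")
        pid = str(grp["participant_id"].iloc[0])
        y = grp[list(spec.symptoms)].to_numpy(dtype=float)
        dayidx = grp["day_index"].to_numpy()
        for t in range(n_cond, len(grp)):
            rows_Y.append(y[t])
            rows_Ylag.append(y[t - 1] - symptom_means)
            for e in spec.exposures:
                xv = grp[e].to_numpy(dtype=float)
                for l in spec.lags:
                    spline_parts[(e, l)].append(np.array([xv[t - l]]))
            for c in effort_cols:
                av = grp[c].to_numpy(dtype=float)
                for l in spec.activity_lags:
                    effort_parts[(c, l)].append(np.array([av[t - l]]))
            part_codes.append(pid_code[pid])
            rows_meta.append((pid, int(dayidx[t]), run_id))
            key = (run_id, t - 1)
            prev_rows.append(row_of.get(key, -1))
            row_of[(run_id, t)] = row_counter
            row_counter += 1

    n = row_counter
    Y = np.vstack(rows_Y)
    Ylag = np.vstack(rows_Ylag)
    part_codes = np.asarray(part_codes, dtype=int)

    col_names: list[str] = ["intercept"]
    cols: list[np.ndarray] = [np.ones(n)]
    col_blocks: dict[tuple[str, int], dict[str, list[int]]] = {}

    for e in spec.exposures:
        t = knots[e]
        ref = rcs_basis(np.array([exposure_means[e]]), t)[0]
        for l in spec.lags:
            xv = np.concatenate(spline_parts[(e, l)])
            basis = rcs_basis(xv, t) - ref  # zero at the grand mean
            ids_lin, ids_nonlin = [], []
            for j in range(basis.shape[1]):
                col_names.append(f"{e}:lag{l}:s{j + 1}")
                cols.append(basis[:, j])
                (ids_lin if j == 0 else ids_nonlin).append(len(col_names) - 1)
            col_blocks[(e, l)] = {
                "linear": ids_lin, "nonlinear": ids_nonlin, "interaction": [],
            }

    if spec.interaction is not None:
        mod_row = modifier[part_codes]
        main_name = (
            "sex[male]" if spec.interaction == "sex" else spec.interaction
        )
        if main_name not in cov_names:
            col_names.append(f"mod[{spec.interaction}]")
            cols.append(mod_row)
        for e in spec.exposures:
            for l in spec.lags:
                base = col_blocks[(e, l)]
                for j, cid in enumerate(base["linear"] + base["nonlinear"]):
                    col_names.append(f"{col_names[cid]}:x:{spec.interaction}")
                    cols.append(cols[cid] * mod_row)
                    base["interaction"].append(len(col_names) - 1)

    for c in effort_cols:
        for l in spec.activity_lags:
            col_names.append(f"{c}:lag{l}")
            cols.append(np.concatenate(effort_parts[(c, l)]) - effort_means[c])

    for name, col in zip(cov_names, cov_mat.T):
        col_names.append(name)
        cols.append(col[part_codes])

    X = np.column_stack(cols)
    meta = pd.DataFrame(rows_meta, columns=["participant_id", "day_index", "run_id"])
    Ymask = np.isfinite(Y)
    if not spec.impute_missing and not Ymask.all():
        raise ValueError(
            "missing symptom values in likelihood rows; enable impute_missing "
            "or filter incomplete days"
        )
    return DesignMatrices(
        Y=Y,
        Ylag=Ylag,
        X=X,
        col_names=col_names,
        participant_index=part_codes,
        participant_ids=participant_ids,
        row_meta=meta,
        spec=spec,
        knots=knots,
        exposure_means=exposure_means,
        exposure_p99=exposure_p99,
        symptom_grand_means=symptom_means,
        col_blocks=col_blocks,
        Ymask=Ymask,
        prev_row=np.asarray(prev_rows, dtype=int),
    )
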