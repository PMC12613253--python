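"""Shared fixtures: small simulated cohorts and fitted models reused across
test modules (session-scoped, since MCMC fits are the expensive part)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import emalag as em
from emalag.design import DesignMatrices, ModelSpec
from emalag.simulate import calibration_config


def make_plain_design(X: np.ndarray, Y: np.ndarray, spec: ModelSpec,
                      participant_index: np.ndarray | None = None,
                      n_participants: int = 1,
                      Ylag: np.ndarray | None = None) -> DesignMatrices:
    """Wrap raw matrices in a DesignMatrices for reduced-model tests."""
    n = X.shape[0]
    K = Y.shape[1]
    if participant_index is None:
        participant_index = np.zeros(n, dtype=int)
    pids = [f"p{i}" for i in range(n_participants)]
    return DesignMatrices(
        Y=Y,
        Ylag=np.zeros((n, K)) if Ylag is None else Ylag,
        X=X,
        col_names=["intercept"] + [f"x{i}" for i in range(1, X.shape[1])],
        participant_index=participant_index,
        participant_ids=pids,
        row_meta=pd.DataFrame({
            "participant_id": [pids[i] for i in participant_index],
            "day_index": np.arange(n), "run_id": ["r0"] * n,
        }),
        spec=spec,
        knots={}, exposure_means={}, exposure_p99={},
        symptom_grand_means=np.nanmean(Y, axis=0),
        col_blocks={},
        Ymask=np.isfinite(Y),
        prev_row=np.full(n, -1, dtype=int),
    )


def prepare(cohort: em.Cohort, center=("stress",)) -> em.DayLevelDataset:
    days = em.filter_consecutive_runs(em.aggregate_to_days(cohort))
    ds, _ = em.grand_mean_center(days, list(center))
    return ds


@pytest.fixture(scope="session")
def calib_cfg():
    """Mid-scale cohort with a known linear stress->fatigue lag-0 effect."""
    return calibration_config(
        30, 12,
        true_effects={
            ("fatigue", "stress", 0): em.EffectSpec(linear=0.5),
            ("anxiety", "stress", 0): em.EffectSpec(linear=0.4),
        },
        seed=101,
    )


@pytest.fixture(scope="session")
def calib_days(calib_cfg):
    return prepare(em.simulate_cohort(calib_cfg))


@pytest.fixture(scope="session")
def calib_fit(calib_cfg, calib_days):
    spec = ModelSpec(
        symptoms=("fatigue", "anxiety", "pain"), exposures=("stress",),
        covariates=(), activity_lags=(),
    )
    design = em.build_design(calib_days, spec)
    draws = em.run_mcmc(design, n_chains=2, n_iter=1200, burn_in=700,
                        seed=102, store_u=False)
    truth = em.ground_truth(calib_cfg, spec, design)
    return draws, truth, design


@pytest.fixture(scope="session")
def full_fit():
    """Small full-surface fit: 8 symptoms x 3 exposures x 3 lags."""
    cfg = calibration_config(
        16, 9,
        true_effects={("anxiety", "stress", 0): em.EffectSpec(linear=0.5)},
        seed=201,
    )
    ds = prepare(em.simulate_cohort(cfg), center=em.EXPOSURES)
    spec = ModelSpec(covariates=("age_years", "sex"))
    design = em.build_design(ds, spec)
    draws = em.run_mcmc(design, n_chains=2, n_iter=500, burn_in=300,
                        seed=202, store_u=False)
    return draws, ds
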