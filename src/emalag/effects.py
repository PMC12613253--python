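"""Posterior summaries: effect curves, joint tests, ICCs, subgroup contrasts.

The reported quantity for an exposure–symptom–lag triple is the change in
mean symptom severity at exposure level ``g`` relative to the grand-mean
exposure level, obtained per posterior draw as ``[s(g) - s(xbar)] . beta``
with ``s`` the restricted-cubic-spline basis — so the curve is exactly zero
at the grand mean by construction.  Credible bounds are posterior 2.5/97.5
percentiles.

"P-values" are a Wald-type bridge from the Bayesian fit: for the block of
linear + nonlinear spline coefficients with posterior mean ``m`` and
posterior covariance ``V``, the statistic ``m' V^{-1} m`` is referred to a
chi-square with block-dimension degrees of freedom.  Raw p-values are
reported without multiple-comparison correction (a deliberate,
hypothesis-generating choice documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import SYMPTOMS, DayLevelDataset
from .mcmc import PosteriorDraws
from .splines import rcs_basis

__all__ = [
    "EffectEstimate",
    "effect_curve",
    "joint_pvalue",
    "icc",
    "subgroup_test",
    "p_value_matrix",
    "write_report",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Change in mean symptom severity at one exposure level vs grand mean."""

    symptom: str
    exposure: str
    lag: int
    exposure_level: float
    delta: float
    cri_low: float
    cri_high: float
    p_joint: float


def _spline_contrast(draws: PosteriorDraws, exposure: str,
                     levels: np.ndarray) -> np.ndarray:
    """Basis differences s(g) - s(grand mean), shape (len(levels), k-1)."""
    knots = np.asarray(draws.knots[exposure], dtype=float)
    ref = float(draws.exposure_means[exposure])
    basis = rcs_basis(levels, knots)
    basis_ref = rcs_basis(np.array([ref]), knots)[0]
    return basis - basis_ref


def _block_ids(draws: PosteriorDraws, exposure: str, lag: int,
               which: tuple[str, ...] = ("linear", "nonlinear")) -> list[int]:
    try:
        block = draws.col_blocks[(exposure, lag)]
    except KeyError:
        raise KeyError(f"({exposure}, lag {lag}) not in fitted model") from None
    ids: list[int] = []
    for part in which:
        ids.extend(block[part])
    return ids


def effect_curve(
    draws: PosteriorDraws,
    exposure: str,
    lag: int,
    symptom: str,
    grid: np.ndarray | None = None,
    level: float = 0.95,
    truncate_p99: bool = True,
    n_grid: int = 41,
) -> list[EffectEstimate]:
    """Posterior effect-vs-grand-mean curve with credible intervals.

    ``grid`` defaults to an even grid from 0 to the 99th centile of the
    observed exposure (the presentation truncation used for the published
    curves); pass ``truncate_p99=False`` to span the full 0–10 scale.
    """
    if symptom not in draws.symptoms:
        raise KeyError(f"symptom {symptom!r} not in fit")
    if grid is None:
        hi = draws.exposure_p99[exposure] if truncate_p99 else 10.0
        grid = np.linspace(0.0, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 10)):
        raise ValueError("exposure grid must lie in [0, 10]")

    ids = _block_ids(draws, exposure, lag)
    beta = draws.flat_beta(symptom, ids)          # (ndraw, k-1)
    contrast = _spline_contrast(draws, exposure, grid)  # (ngrid, k-1)
    delta_draws = contrast @ beta.T               # (ngrid, ndraw)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    delta = delta_draws.mean(axis=1)
    lo = np.quantile(delta_draws, lo_q, axis=1)
    hi = np.quantile(delta_draws, hi_q, axis=1)
    p = joint_pvalue(draws, exposure, lag, symptom)
    return [
        EffectEstimate(symptom, exposure, lag, float(g), float(d),
                       float(l), float(h), p)
        for g, d, l, h in zip(grid, delta, lo, hi)
    ]


def joint_pvalue(draws: PosteriorDraws, exposure: str, lag: int,
                 symptom: str) -> float:
    """Joint Wald-type test of the linear + nonlinear spline block."""
    ids = _block_ids(draws, exposure, lag)
    beta = draws.flat_beta(symptom, ids)
    m = beta.mean(axis=0)
    V = np.cov(beta.T).reshape(len(ids), len(ids))
    try:
        Vim = np.linalg.solve(V, m)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular posterior covariance for the spline block; "
            "run longer chains"
        ) from None
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "near-singular posterior covariance for the spline block; "
            "run longer chains"
        )
    W = float(m @ Vim)
    return float(stats.chi2.sf(W, df=len(ids)))


def linear_tail_probability(draws: PosteriorDraws, exposure: str, lag: int,
                            symptom: str) -> float:
    """Two-sided posterior tail probability for the linear coefficient only.

    The Bayesian alternative to the 1-df Wald bridge: twice the smaller of
    P(beta > 0) and P(beta < 0).
    """
    ids = _block_ids(draws, exposure, lag, which=("linear",))
    b = draws.flat_beta(symptom, ids)[:, 0]
    p_pos = float(np.mean(b > 0))
    return float(min(1.0, 2 * min(p_pos, 1 - p_pos)))


def icc(dataset: DayLevelDataset, symptoms: tuple[str, ...] = SYMPTOMS
        ) -> pd.Series:
    """Design-based one-way random-effects ICC per symptom.

    ANOVA moment estimator on day-level scores grouped by participant:
    ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW), with n0 the standard
    adjusted mean group size.  NaN (flagged) when within-participant
    variance is zero everywhere.
    """
    days = dataset.days
    groups = days.groupby("participant_id")
    a = groups.ngroups
    if a < 2:
        raise ValueError("ICC needs at least 2 participants")
    sizes = groups.size().to_numpy(dtype=float)
    if (sizes < 2).all():
        raise ValueError("ICC needs repeated days within participants")
    N = sizes.sum()
    n0 = (N - (sizes ** 2).sum() / N) / (a - 1)
    out = {}
    for s in symptoms:
        y = days[s]
        grand = y.mean()
        means = groups[s].mean()
        ssb = float((sizes * (means - grand) ** 2).sum())
        ssw = float(((y - means.loc[days["participant_id"]].to_numpy()) ** 2).sum())
        msb = ssb / (a - 1)
        msw = ssw / (N - a)
        if msw == 0 and msb == 0:
            out[s] = np.nan
        else:
            out[s] = (msb - msw) / (msb + (n0 - 1) * msw)
    return pd.Series(out, name="icc")


def subgroup_test(
    draws: PosteriorDraws,
    exposure: str,
    lag: int,
    symptom: str,
    modifier: str,
    grid: np.ndarray | None = None,
) -> tuple[float, dict[str, list[EffectEstimate]]]:
    """Joint interaction test plus per-stratum effect curves.

    The p-value is the Wald-type test over all modifier × spline columns
    for the (exposure, lag) block; the curves give the effect-vs-grand-mean
    contrast separately in the reference stratum (modifier = 0) and the
    index stratum (modifier = 1).
    """
    block = draws.col_blocks.get((exposure, lag))
    if block is None or not block.get("interaction"):
        raise ValueError(
            f"fit contains no {modifier!r} interaction for ({exposure}, lag {lag})"
        )
    int_ids = list(block["interaction"])
    base_ids = _block_ids(draws, exposure, lag)

    beta_int = draws.flat_beta(symptom, int_ids)
    m = beta_int.mean(axis=0)
    V = np.cov(beta_int.T).reshape(len(int_ids), len(int_ids))
    W = float(m @ np.linalg.solve(V, m))
    p = float(stats.chi2.sf(W, df=len(int_ids)))

    if grid is None:
        grid = np.linspace(0.0, draws.exposure_p99[exposure], 41)
    grid = np.asarray(grid, dtype=float)
    contrast = _spline_contrast(draws, exposure, grid)
    beta_base = draws.flat_beta(symptom, base_ids)
    curves = {}
    for label, beta in (
        ("reference", beta_base),
        ("index", beta_base + beta_int),
    ):
        dd = contrast @ beta.T
        delta = dd.mean(axis=1)
        lo = np.quantile(dd, 0.025, axis=1)
        hi = np.quantile(dd, 0.975, axis=1)
        curves[label] = [
            EffectEstimate(symptom, exposure, lag, float(g), float(d),
                           float(l), float(h), p)
            for g, d, l, h in zip(grid, delta, lo, hi)
        ]
    return p, curves


def p_value_matrix(draws: PosteriorDraws) -> pd.DataFrame:
    """Joint p-values for every symptom × exposure × lag cell.

    One row per symptom; columns ``{exposure}:lag{l}`` — with the default 8
    symptoms, 3 exposures and 3 lags, exactly 72 cells.
    """
    cols = {}
    for e in draws.exposures:
        for l in draws.lags:
            cols[f"{e}:lag{l}"] = [
                joint_pvalue(draws, e, l, s) for s in draws.symptoms
            ]
    return pd.DataFrame(cols, index=pd.Index(draws.symptoms, name="symptom"))


def write_report(
    draws: PosteriorDraws,
    dataset: DayLevelDataset | None,
    out_dir: str | Path,
    n_grid: int = 41,
) -> dict[str, Path]:
    """Write the reporting tables: effects CSV (one row per grid point per
    symptom × exposure × lag), p-value matrix CSV, and ICC CSV when a
    day-level dataset is supplied."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for e in draws.exposures:
        for l in draws.lags:
            for s in draws.symptoms:
                for est in effect_curve(draws, e, l, s, n_grid=n_grid):
                    rows.append(est.__dict__)
    effects = pd.DataFrame(rows)
    paths["effects"] = out / "effects.csv"
    effects.to_csv(paths["effects"], index=False, float_format="%.17g")

    pmat = p_value_matrix(draws)
    paths["p_values"] = out / "p_values.csv"
    pmat.to_csv(paths["p_values"], float_format="%.17g")

    if dataset is not None:
        symptoms = tuple(draws.symptoms)
        paths["icc"] = out / "icc.csv"
        icc(dataset, symptoms).rename_axis("symptom").to_csv(
            paths["icc"], float_format="%.17g"
        )
    return paths
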