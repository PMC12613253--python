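"""Gibbs sampler for the joint multivariate hierarchical AR(1) model.

Model, for likelihood row (participant i, day t) and symptom k:

    y_itk = x_it' b_k + rho_k * (y_{i,t-1,k} - ybar_k) + u_ik + eps_itk
    eps_it ~ N_K(0, Sigma)        (unstructured K x K, K symptoms)
    u_ik   ~ N(0, tau_k^2)

with priors: b ~ normal (vague, see PriorSpec), rho_k ~ uniform(-1, 1),
tau_k ~ half-normal, Sigma ~ inverse-Wishart.  All full conditionals are
conjugate except tau_k, which is updated by univariate slice sampling:

* b_k — multivariate normal, obtained by reducing the K-variate likelihood
  to the Gaussian conditional of symptom k given the other symptoms' current
  residuals (mean shift c_itk = -(1/W_kk) sum_{j!=k} W_kj r_itj and variance
  1/W_kk, with W = Sigma^{-1});
* rho_k — normal truncated to (-1, 1), drawn exactly by inverse-CDF;
* u_i — K-variate normal;
* Sigma — inverse-Wishart;
* missing outcomes (opt-in) — drawn from their Gaussian full conditional,
  combining the same-day cross-symptom information and the next day's AR
  term, i.e. posterior-predictive imputation inside the sweep.

Chains are run sequentially with independent seeds spawned from the master
seed, so results are exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .design import DesignMatrices, ModelSpec, PriorSpec

__all__ = ["PosteriorDraws", "run_mcmc", "diagnostics"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class PosteriorDraws:
    """Posterior samples with chain structure plus the design metadata the
    reporting stage needs (column names, spline knots, grand means)."""

    beta: np.ndarray            # (chains, draws, p, K)
    rho: np.ndarray             # (chains, draws, K)
    tau: np.ndarray             # (chains, draws, K)
    sigma: np.ndarray           # (chains, draws, K, K)
    u: np.ndarray | None        # (chains, draws, nP, K) or None
    col_names: list[str]
    symptoms: list[str]
    exposures: list[str]
    lags: list[int]
    col_blocks: dict[tuple[str, int], dict[str, list[int]]]
    knots: dict[str, np.ndarray]
    exposure_means: dict[str, float]
    exposure_p99: dict[str, float]
    participant_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def flat_beta(self, symptom: str, col_ids: list[int]) -> np.ndarray:
        """Pooled (chains*draws, len(col_ids)) draws of chosen coefficients."""
        k = self.symptoms.index(symptom)
        sub = self.beta[:, :, col_ids, k]
        return sub.reshape(-1, len(col_ids))

    def col_id(self, name: str) -> int:
        return self.col_names.index(name)

    def to_arviz(self):
        import arviz as az

        data = {
            "beta": self.beta,
            "rho": self.rho,
            "tau": self.tau,
            "sigma": self.sigma,
        }
        coords = {
            "column": self.col_names,
            "symptom": self.symptoms,
            "symptom2": self.symptoms,
        }
        dims = {
            "beta": ["column", "symptom"],
            "rho": ["symptom"],
            "tau": ["symptom"],
            "sigma": ["symptom", "symptom2"],
        }
        if self.u is not None:
            data["u"] = self.u
            coords["participant"] = self.participant_ids
            dims["u"] = ["participant", "symptom"]
        return az.from_dict(posterior=data, coords=coords, dims=dims)

    # -- persistence (long-format CSV + JSON manifest) --------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = []
        c, d, p, K = self.beta.shape
        chain = np.repeat(np.arange(c), d)
        it = np.tile(np.arange(d), c)
        for j, col in enumerate(self.col_names):
            for k, s in enumerate(self.symptoms):
                frames.append(pd.DataFrame({
                    "chain": chain, "iteration": it,
                    "parameter": f"beta[{s}][{col}]",
                    "value": self.beta[:, :, j, k].ravel(),
                }))
        for k, s in enumerate(self.symptoms):
            frames.append(pd.DataFrame({
                "chain": chain, "iteration": it,
                "parameter": f"rho[{s}]", "value": self.rho[:, :, k].ravel()}))
            frames.append(pd.DataFrame({
                "chain": chain, "iteration": it,
                "parameter": f"tau[{s}]", "value": self.tau[:, :, k].ravel()}))
        for k1, s1 in enumerate(self.symptoms):
            for k2, s2 in enumerate(self.symptoms):
                if k2 < k1:
                    continue
                frames.append(pd.DataFrame({
                    "chain": chain, "iteration": it,
                    "parameter": f"sigma[{s1},{s2}]",
                    "value": self.sigma[:, :, k1, k2].ravel()}))
        pd.concat(frames, ignore_index=True).to_csv(
            out / "draws.csv", index=False, float_format="%.17g"
        )
        manifest = {
            "columns": self.col_names,
            "symptoms": self.symptoms,
            "exposures": self.exposures,
            "lags": self.lags,
            "col_blocks": {
                f"{e}|{l}": blocks for (e, l), blocks in self.col_blocks.items()
            },
            "knots": {e: list(map(float, v)) for e, v in self.knots.items()},
            "exposure_means": self.exposure_means,
            "exposure_p99": self.exposure_p99,
            "n_chains": int(self.n_chains),
            "n_draws": int(self.n_draws),
            "meta": self.meta,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "PosteriorDraws":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        long = pd.read_csv(src / "draws.csv", float_precision="round_trip")
        c, d = manifest["n_chains"], manifest["n_draws"]
        cols, symptoms = manifest["columns"], manifest["symptoms"]
        p, K = len(cols), len(symptoms)
        by_param = {
            name: grp.sort_values(["chain", "iteration"])["value"]
            .to_numpy().reshape(c, d)
            for name, grp in long.groupby("parameter", sort=False)
        }
        beta = np.empty((c, d, p, K))
        rho = np.empty((c, d, K))
        tau = np.empty((c, d, K))
        sigma = np.empty((c, d, K, K))
        for j, col in enumerate(cols):
            for k, s in enumerate(symptoms):
                beta[:, :, j, k] = by_param[f"beta[{s}][{col}]"]
        for k, s in enumerate(symptoms):
            rho[:, :, k] = by_param[f"rho[{s}]"]
            tau[:, :, k] = by_param[f"tau[{s}]"]
        for k1, s1 in enumerate(symptoms):
            for k2, s2 in enumerate(symptoms):
                a, b = sorted((k1, k2))
                sigma[:, :, k1, k2] = by_param[
                    f"sigma[{symptoms[a]},{symptoms[b]}]"
                ]
        blocks = {}
        for key, v in manifest["col_blocks"].items():
            e, l = key.rsplit("|", 1)
            blocks[(e, int(l))] = v
        return cls(
            beta=beta, rho=rho, tau=tau, sigma=sigma, u=None,
            col_names=cols, symptoms=symptoms,
            exposures=manifest["exposures"], lags=manifest["lags"],
            col_blocks=blocks,
            knots={e: np.asarray(v) for e, v in manifest["knots"].items()},
            exposure_means=manifest["exposure_means"],
            exposure_p99=manifest["exposure_p99"],
            meta=manifest.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# sampling utilities


def _truncnorm_draw(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    if b - a < 1e-14:  # numerically degenerate: pin to nearest bound
        return float(np.clip(mean, lo + 1e-9, hi - 1e-9))
    u = rng.uniform(a, b)
    return float(mean + sd * ndtri(u))


def _slice_sample(x0: float, logf, rng, width: float = 1.0,
                  lower: float = 0.0, max_steps: int = 50) -> float:
    """Univariate stepping-out slice sampler on (lower, inf)."""
    logy = logf(x0) + np.log(rng.uniform())
    L = x0 - width * rng.uniform()
    R = L + width
    L = max(L, lower + 1e-12)
    steps = max_steps
    while steps > 0 and L > lower + 1e-12 and logf(L) > logy:
        L = max(L - width, lower + 1e-12)
        steps -= 1
    steps = max_steps
    while steps > 0 and logf(R) > logy:
        R += width
        steps -= 1
    while True:
        x1 = rng.uniform(L, R)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1


def _mvn_from_precision(prec: np.ndarray, rhs: np.ndarray, rng) -> np.ndarray:
    """Draw N(prec^{-1} rhs, prec^{-1}) via Cholesky of the precision."""
    c, low = linalg.cho_factor(prec, lower=True, check_finite=False)
    mean = linalg.cho_solve((c, low), rhs, check_finite=False)
    z = rng.standard_normal(prec.shape[0])
    return mean + linalg.solve_triangular(c.T, z, lower=False, check_finite=False)


# ---------------------------------------------------------------------------
# main sampler


def run_mcmc(
    design: DesignMatrices,
    n_chains: int = 4,
    n_iter: int = 5000,
    burn_in: int = 2500,
    seed: int = 0,
    thin: int = 1,
    store_u: bool = True,
    prior_only: bool = False,
    fix_sigma: np.ndarray | None = None,
) -> PosteriorDraws:
    """Fit the joint model by Gibbs sampling and return post-burn-in draws.

    ``prior_only`` replaces the posterior with independent draws from the
    priors (a prior-sample check for the sampler's distributions).
    ``fix_sigma`` holds the residual covariance at a known value instead of
    sampling it, which makes reduced models exactly conjugate.
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    spec = design.spec
    K = design.n_symptoms
    p = design.n_cols
    n = design.n_rows
    if not prior_only and n <= p:
        raise ValueError("design is degenerate: rows must exceed columns")

    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    n_keep = n_iter // thin
    nP = len(design.participant_ids)
    out_beta = np.empty((n_chains, n_keep, p, K))
    out_rho = np.zeros((n_chains, n_keep, K))
    out_tau = np.zeros((n_chains, n_keep, K))
    out_sigma = np.empty((n_chains, n_keep, K, K))
    out_u = np.zeros((n_chains, n_keep, nP, K)) if store_u else None

    for ci in range(n_chains):
        rng = np.random.default_rng(seeds[ci])
        if prior_only:
            _sample_prior(spec.priors, spec, K, p, nP, n_keep, rng,
                          out_beta[ci], out_rho[ci], out_tau[ci],
                          out_sigma[ci], None if out_u is None else out_u[ci],
                          fix_sigma)
            continue
        _run_chain(design, spec, n_iter, burn_in, thin, rng, fix_sigma,
                   out_beta[ci], out_rho[ci], out_tau[ci], out_sigma[ci],
                   None if out_u is None else out_u[ci])

    return PosteriorDraws(
        beta=out_beta, rho=out_rho, tau=out_tau, sigma=out_sigma, u=out_u,
        col_names=list(design.col_names),
        symptoms=list(spec.symptoms),
        exposures=list(spec.exposures),
        lags=list(spec.lags),
        col_blocks=design.col_blocks,
        knots=design.knots,
        exposure_means=design.exposure_means,
        exposure_p99=design.exposure_p99,
        participant_ids=list(design.participant_ids),
        meta={
            "seed": int(seed), "n_chains": int(n_chains), "n_iter": int(n_iter),
            "burn_in": int(burn_in), "thin": int(thin),
            "prior_only": bool(prior_only),
            "ar1": bool(spec.ar1), "random_intercepts": bool(spec.random_intercepts),
        },
    )


def _sample_prior(priors: PriorSpec, spec: ModelSpec, K, p, nP, n_keep, rng,
                  o_beta, o_rho, o_tau, o_sigma, o_u, fix_sigma) -> None:
    sds = np.full(p, priors.coef_sd)
    means = np.zeros(p)
    sds[0], means[0] = priors.intercept_sd, priors.intercept_mean
    for i in range(n_keep):
        o_beta[i] = means[:, None] + sds[:, None] * rng.standard_normal((p, K))
        if spec.ar1:
            o_rho[i] = rng.uniform(-1, 1, K)
        if spec.random_intercepts:
            o_tau[i] = np.abs(rng.standard_normal(K)) * priors.tau_scale
        if fix_sigma is not None:
            o_sigma[i] = fix_sigma
        else:
            o_sigma[i] = invwishart.rvs(
                df=K + priors.sigma_extra_df,
                scale=priors.sigma_scale * np.eye(K), random_state=rng,
            ).reshape(K, K)
        if o_u is not None and spec.random_intercepts:
            o_u[i] = rng.standard_normal((nP, K)) * o_tau[i]


def _run_chain(design: DesignMatrices, spec: ModelSpec, n_iter, burn_in, thin,
               rng, fix_sigma, o_beta, o_rho, o_tau, o_sigma, o_u) -> None:
    priors = spec.priors
    K, p, n = design.n_symptoms, design.n_cols, design.n_rows
    X = design.X
    Y = design.Y.copy()
    Z = design.Ylag.copy()
    part = design.participant_index
    nP = len(design.participant_ids)
    n_per = np.bincount(part, minlength=nP).astype(float)
    mask_missing = ~design.Ymask
    any_missing = mask_missing.any()
    if any_missing and not spec.impute_missing:
        raise ValueError("missing outcomes present but impute_missing is off")
    if any_missing:
        # start imputed values at the symptom grand mean
        gm = design.symptom_grand_means
        miss_r, miss_k = np.nonzero(mask_missing)
        Y[miss_r, miss_k] = gm[miss_k]
        next_row = np.full(n, -1, dtype=int)
        pr = design.prev_row
        next_row[pr[pr >= 0]] = np.nonzero(pr >= 0)[0]
        lag_nan = ~np.isfinite(Z)
        if lag_nan.any():
            rlag, klag = np.nonzero(lag_nan)
            Z[rlag, klag] = 0.0
        missing_entries = list(zip(miss_r.tolist(), miss_k.tolist()))
    else:
        missing_entries = []

    XtX = X.T @ X
    prior_prec = np.full(p, priors.coef_sd ** -2)
    prior_prec[0] = priors.intercept_sd ** -2
    prior_rhs = np.zeros(p)
    prior_rhs[0] = priors.intercept_mean * prior_prec[0]

    # initial state: ridge least squares + jitter, for overdispersed starts
    B = np.empty((p, K))
    ridge = XtX + np.eye(p)
    for k in range(K):
        B[:, k] = linalg.solve(ridge, X.T @ Y[:, k], assume_a="pos")
    B += 0.25 * rng.standard_normal((p, K))
    rho = np.zeros(K)
    if spec.ar1:
        rho = rng.uniform(-0.3, 0.3, K)
    U = np.zeros((nP, K))
    tau = np.abs(rng.normal(1.0, 0.25, K)) + 0.25
    fitted = X @ B + rho * Z + U[part]
    E0 = Y - fitted
    Sigma = fix_sigma.copy() if fix_sigma is not None else (
        np.cov(E0.T).reshape(K, K) + 0.1 * np.eye(K)
    )

    total = burn_in + n_iter
    kept = 0
    for sweep in range(total):
        W = linalg.inv(Sigma)
        s2 = 1.0 / np.diag(W)  # conditional variances given other symptoms

        fitted = X @ B + rho * Z + U[part]
        R = Y - fitted

        # --- impute missing outcomes from their full conditional ---------
        for (t, k) in missing_entries:
            mu_tk = fitted[t, k]
            c_tk = -(R[t] @ W[:, k] - R[t, k] * W[k, k]) / W[k, k]
            prec = W[k, k]
            mean_acc = (mu_tk + c_tk) * prec
            t2 = next_row[t] if any_missing else -1
            if t2 >= 0 and spec.ar1 and abs(rho[k]) > 1e-12:
                mu_star = fitted[t2, k] - rho[k] * Z[t2, k]
                c_t2 = -(R[t2] @ W[:, k] - R[t2, k] * W[k, k]) / W[k, k]
                target = (Y[t2, k] - mu_star - c_t2) / rho[k] \
                    + design.symptom_grand_means[k]
                prec_b = rho[k] ** 2 * W[k, k]
                prec += prec_b
                mean_acc += prec_b * target
            y_new = mean_acc / prec + rng.standard_normal() / np.sqrt(prec)
            Y[t, k] = y_new
            R[t, k] = y_new - fitted[t, k]
            if t2 >= 0:
                z_new = y_new - design.symptom_grand_means[k]
                delta = rho[k] * (z_new - Z[t2, k])
                Z[t2, k] = z_new
                fitted[t2, k] += delta
                R[t2, k] -= delta

        # --- fixed effects and AR coefficients, symptom by symptom -------
        for k in range(K):
            c_k = -(R @ W[:, k] - R[:, k] * W[k, k]) / W[k, k]
            ystar = Y[:, k] - c_k
            w = ystar - rho[k] * Z[:, k] - U[part, k]
            prec = XtX / s2[k] + np.diag(prior_prec)
            rhs = X.T @ w / s2[k] + prior_rhs
            B[:, k] = _mvn_from_precision(prec, rhs, rng)
            xb = X @ B[:, k]
            if spec.ar1:
                v = ystar - xb - U[part, k]
                zz = float(Z[:, k] @ Z[:, k])
                if zz > 1e-12:
                    m_r = float(Z[:, k] @ v) / zz
                    sd_r = np.sqrt(s2[k] / zz)
                    rho[k] = _truncnorm_draw(m_r, sd_r, -1.0, 1.0, rng)
                else:
                    rho[k] = rng.uniform(-1, 1)
            # refresh this symptom's residual before the next one uses it
            fitted[:, k] = xb + rho[k] * Z[:, k] + U[part, k]
            R[:, k] = Y[:, k] - fitted[:, k]

        # --- random intercepts -------------------------------------------
        if spec.random_intercepts:
            e_noU = Y - (X @ B + rho * Z)
            SE = np.zeros((nP, K))
            np.add.at(SE, part, e_noU)
            WSE = SE @ W.T
            tau_prec = np.diag(1.0 / tau ** 2)
            for i in range(nP):
                if n_per[i] == 0:
                    U[i] = rng.standard_normal(K) * tau
                    continue
                prec_i = n_per[i] * W + tau_prec
                U[i] = _mvn_from_precision(prec_i, WSE[i], rng)
            # --- random-intercept scales (slice sampling) -----------------
            for k in range(K):
                ssq = float(U[:, k] @ U[:, k])
                scale2 = priors.tau_scale ** 2

                def logf(t, ssq=ssq, scale2=scale2):
                    return (-nP * np.log(t) - ssq / (2 * t * t)
                            - t * t / (2 * scale2))

                tau[k] = _slice_sample(tau[k], logf, rng, width=0.5)

        # --- residual covariance -----------------------------------------
        E = Y - (X @ B + rho * Z + U[part])
        if fix_sigma is None:
            df = n + K + priors.sigma_extra_df
            scale = priors.sigma_scale * np.eye(K) + E.T @ E
            Sigma = invwishart.rvs(df=df, scale=scale, random_state=rng)
            Sigma = np.asarray(Sigma).reshape(K, K)
        if not np.all(np.isfinite(B)) or not np.all(np.isfinite(Sigma)):
            raise FloatingPointError(
                f"sampler diverged at sweep {sweep}: non-finite state"
            )

        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            o_beta[kept] = B
            o_rho[kept] = rho
            o_tau[kept] = tau
            o_sigma[kept] = Sigma
            if o_u is not None:
                o_u[kept] = U
            kept += 1


# ---------------------------------------------------------------------------
# convergence diagnostics


def diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split R-hat and bulk ESS for every scalar parameter.

    Returns a table with one row per parameter and a ``flagged`` column for
    R-hat above ``rhat_threshold``.  Requires at least two chains.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("diagnostics need at least 2 chains")
    idata = draws.to_arviz()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for var in ("beta", "rho", "tau", "sigma"):
        r = np.asarray(rhat[var]).ravel()
        e = np.asarray(ess[var]).ravel()
        names = _scalar_names(draws, var)
        for name, ri, ei in zip(names, r, e):
            rows.append((name, float(ri), float(ei)))
    out = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk"])
    out["flagged"] = out["rhat"] > rhat_threshold
    return out


def _scalar_names(draws: PosteriorDraws, var: str) -> list[str]:
    if var == "beta":
        return [
            f"beta[{s}][{c}]" for c in draws.col_names for s in draws.symptoms
        ]
    if var in ("rho", "tau"):
        return [f"{var}[{s}]" for s in draws.symptoms]
    return [
        f"sigma[{s1},{s2}]" for s1 in draws.symptoms for s2 in draws.symptoms
    ]
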