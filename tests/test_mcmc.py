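"""Gibbs sampler: conjugate oracles, priors, determinism, diagnostics."""

import numpy as np
import pytest

import emalag as em
from emalag.design import ModelSpec, PriorSpec
from emalag.mcmc import PosteriorDraws, diagnostics, run_mcmc

from conftest import make_plain_design, prepare
from emalag.simulate import calibration_config

REDUCED = dict(symptoms=("fatigue",), exposures=(), lags=(0,), covariates=(),
               activity_lags=(), ar1=False, random_intercepts=False)


def _closed_form_posterior(X, y, sigma2, priors: PriorSpec):
    p = X.shape[1]
    P0 = np.full(p, priors.coef_sd ** -2)
    P0[0] = priors.intercept_sd ** -2
    prec = X.T @ X / sigma2 + np.diag(P0)
    rhs = X.T @ y / sigma2
    rhs[0] += priors.intercept_mean * P0[0]
    cov = np.linalg.inv(prec)
    return cov @ rhs, np.sqrt(np.diag(cov))


class TestConjugateOracle:
    @pytest.mark.parametrize("n,p,sigma2,seed", [
        (120, 4, 1.3, 0),
        (60, 2, 0.4, 1),
        (200, 6, 2.5, 2),
    ])
    def test_reduced_model_matches_closed_form(self, n, p, sigma2, seed):
        """With known sigma^2, no AR and no random effects the posterior of
        beta is exactly normal; the sampler then produces independent exact
        draws, so agreement is within plain Monte-Carlo error."""
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        beta_true = rng.uniform(-1, 2, p)
        y = X @ beta_true + rng.standard_normal(n) * np.sqrt(sigma2)
        spec = ModelSpec(**REDUCED)
        design = make_plain_design(X, y[:, None], spec)
        draws = run_mcmc(design, n_chains=4, n_iter=2000, burn_in=200,
                         seed=seed + 10, fix_sigma=np.array([[sigma2]]),
                         store_u=False)
        b = draws.beta[:, :, :, 0].reshape(-1, p)
        mean_cf, sd_cf = _closed_form_posterior(X, y, sigma2, spec.priors)
        mcse = sd_cf / np.sqrt(b.shape[0])
        assert np.all(np.abs(b.mean(axis=0) - mean_cf) < 3 * mcse)
        assert np.allclose(b.std(axis=0), sd_cf, rtol=0.06)

    def test_matches_ols_oracle_at_vague_prior(self):
        """Independent cross-check: at a vague prior the posterior mean is
        numerically the OLS fit from statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 150
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = X @ np.array([1.0, 0.8, -0.5, 0.2]) + rng.standard_normal(n)
        spec = ModelSpec(**REDUCED)
        design = make_plain_design(X, y[:, None], spec)
        draws = run_mcmc(design, n_chains=2, n_iter=3000, burn_in=200, seed=4,
                         fix_sigma=np.array([[1.0]]), store_u=False)
        ols = sm.OLS(y, X).fit()
        b = draws.beta[:, :, :, 0].reshape(-1, 4).mean(axis=0)
        assert np.allclose(b, ols.params, atol=0.02)

    def test_zero_variance_data_intercept_concentrates(self):
        n = 60
        y = np.full((n, 1), 4.0)
        spec = ModelSpec(**REDUCED)
        design = make_plain_design(np.ones((n, 1)), y, spec)
        draws = run_mcmc(design, n_chains=2, n_iter=1000, burn_in=500, seed=1,
                         store_u=False)
        b = draws.beta[:, :, 0, 0]
        assert b.mean() == pytest.approx(4.0, abs=0.1)
        assert b.std() < 0.15


class TestDeterminismAndShape:
    def test_same_seed_reproduces_draws(self, calib_fit):
        draws, _, design = calib_fit
        again = run_mcmc(design, n_chains=2, n_iter=1200, burn_in=700,
                         seed=102, store_u=False)
        assert np.array_equal(draws.beta, again.beta)
        assert np.array_equal(draws.sigma, again.sigma)

    def test_different_seed_differs(self, calib_fit):
        draws, _, design = calib_fit
        other = run_mcmc(design, n_chains=1, n_iter=50, burn_in=50,
                         seed=999, store_u=False)
        assert not np.allclose(draws.beta[0, :50], other.beta[0])

    def test_degenerate_design_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 8))
        spec = ModelSpec(**REDUCED)
        design = make_plain_design(X, rng.standard_normal((5, 1)), spec)
        with pytest.raises(ValueError, match="degenerate"):
            run_mcmc(design, n_chains=1, n_iter=10, burn_in=0, seed=0)

    def test_save_load_roundtrip(self, calib_fit, tmp_path):
        draws, _, _ = calib_fit
        draws.save(tmp_path / "d")
        back = PosteriorDraws.load(tmp_path / "d")
        assert np.array_equal(back.beta, draws.beta)
        assert np.array_equal(back.rho, draws.rho)
        assert np.array_equal(back.sigma, draws.sigma)
        assert back.col_names == draws.col_names
        assert back.col_blocks[("stress", 0)]["linear"] \
            == draws.col_blocks[("stress", 0)]["linear"]


class TestPriorSample:
    def test_prior_only_moments_match_priorspec(self):
        priors = PriorSpec(sigma_extra_df=4.0)
        spec = ModelSpec(symptoms=("fatigue", "anxiety"), exposures=(),
                         lags=(0,), covariates=(), activity_lags=(),
                         priors=priors)
        rng = np.random.default_rng(0)
        design = make_plain_design(np.ones((10, 1)),
                                   rng.standard_normal((10, 2)), spec)
        draws = run_mcmc(design, n_chains=2, n_iter=4000, burn_in=0, seed=3,
                         prior_only=True)
        n = draws.beta.shape[0] * draws.beta.shape[1]
        # intercept prior N(5, 10)
        b0 = draws.beta[:, :, 0, 0].ravel()
        assert b0.mean() == pytest.approx(5.0, abs=4 * 10 / np.sqrt(n))
        assert b0.std() == pytest.approx(10.0, rel=0.05)
        # rho ~ uniform(-1, 1)
        r = draws.rho.ravel()
        assert r.mean() == pytest.approx(0.0, abs=0.05)
        assert r.std() == pytest.approx(np.sqrt(1 / 3), rel=0.05)
        # tau ~ half-normal(5): mean 5 sqrt(2/pi)
        t = draws.tau.ravel()
        assert t.mean() == pytest.approx(5 * np.sqrt(2 / np.pi), rel=0.05)
        # sigma ~ IW(K + 4, I): E[diag] = 1 / (extra_df + 1) = 1/3... for
        # K = 2, df = 6: E = I / (df - K - 1) = I / 3
        s = draws.sigma[:, :, 0, 0].ravel()
        assert s.mean() == pytest.approx(1 / 3, rel=0.15)


class TestLabelInvariance:
    def test_symptom_order_permutes_but_does_not_change_inference(self):
        cfg = calibration_config(
            20, 10, true_effects={("fatigue", "stress", 0): em.EffectSpec(0.5)},
            seed=55,
        )
        ds = prepare(em.simulate_cohort(cfg))
        kw = dict(exposures=("stress",), covariates=(), activity_lags=())
        d1 = em.build_design(ds, ModelSpec(symptoms=("fatigue", "anxiety"), **kw))
        d2 = em.build_design(ds, ModelSpec(symptoms=("anxiety", "fatigue"), **kw))
        dr1 = run_mcmc(d1, n_chains=2, n_iter=1500, burn_in=700, seed=7,
                       store_u=False)
        dr2 = run_mcmc(d2, n_chains=2, n_iter=1500, burn_in=700, seed=8,
                       store_u=False)
        cid = dr1.col_id("stress:lag0:s1")
        b1 = dr1.flat_beta("fatigue", [cid])[:, 0]
        b2 = dr2.flat_beta("fatigue", [cid])[:, 0]
        tol = 4 * np.hypot(b1.std(), b2.std()) / np.sqrt(200)  # generous MCSE
        assert abs(b1.mean() - b2.mean()) < tol
        assert abs(b1.std() - b2.std()) / b1.std() < 0.2


class TestImputation:
    def test_missing_outcomes_imputed_when_enabled(self, calib_days):
        ds = calib_days.copy()
        # knock out a few internal fatigue day-values (not run-starts)
        idx = ds.days.groupby("run_id").nth(4).index[:5]
        ds.days.loc[idx, "fatigue"] = np.nan
        spec = ModelSpec(symptoms=("fatigue", "anxiety"), exposures=("stress",),
                         covariates=(), activity_lags=(), impute_missing=True)
        design = em.build_design(ds, spec)
        assert (~design.Ymask).sum() == 5
        draws = run_mcmc(design, n_chains=2, n_iter=600, burn_in=400, seed=9,
                         store_u=False)
        cid = draws.col_id("stress:lag0:s1")
        b = draws.flat_beta("fatigue", [cid])[:, 0]
        # a handful of imputed days should not destroy the effect estimate
        assert b.mean() == pytest.approx(0.5, abs=4 * b.std())

    def test_missing_outcomes_rejected_when_disabled(self, calib_days):
        ds = calib_days.copy()
        idx = ds.days.groupby("run_id").nth(4).index[:2]
        ds.days.loc[idx, "fatigue"] = np.nan
        spec = ModelSpec(symptoms=("fatigue",), exposures=("stress",),
                         covariates=(), activity_lags=())
        with pytest.raises(ValueError, match="impute_missing"):
            em.build_design(ds, spec)


class TestDiagnostics:
    def _draws_from_arrays(self, beta):
        c, d = beta.shape[:2]
        K = 1
        return PosteriorDraws(
            beta=beta.reshape(c, d, 1, K),
            rho=np.zeros((c, d, K)), tau=np.ones((c, d, K)),
            sigma=np.ones((c, d, K, K)), u=None,
            col_names=["intercept"], symptoms=["fatigue"],
            exposures=[], lags=[], col_blocks={}, knots={},
            exposure_means={}, exposure_p99={},
        )

    def test_iid_chains_rhat_near_one_and_ess_near_n(self):
        rng = np.random.default_rng(0)
        beta = rng.standard_normal((4, 1000))
        d = self._draws_from_arrays(beta)
        table = diagnostics(d)
        row = table[table["parameter"] == "beta[fatigue][intercept]"].iloc[0]
        assert row["rhat"] == pytest.approx(1.0, abs=0.01)
        assert row["ess_bulk"] == pytest.approx(4000, rel=0.2)
        assert not row["flagged"]

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        beta = np.stack([rng.standard_normal(500),
                         rng.standard_normal(500) + 10])
        table = diagnostics(self._draws_from_arrays(beta))
        row = table[table["parameter"] == "beta[fatigue][intercept]"].iloc[0]
        # rank-normalized split R-hat saturates well above the 1.05 flag
        # threshold for chains with disjoint supports
        assert row["rhat"] > 1.5
        assert row["flagged"]

    def test_single_chain_rejected(self):
        beta = np.random.default_rng(2).standard_normal((1, 100))
        with pytest.raises(ValueError, match="2 chains"):
            diagnostics(self._draws_from_arrays(beta))
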