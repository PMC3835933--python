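"""Gibbs sampler correctness: conjugate oracle, recovery, summaries,
diagnostics, reproducibility."""

import numpy as np
import pytest

import allobayes as ab
from allobayes.gibbs import McmcConfig
from allobayes.summaries import summarize_chain


def make_data(n, alpha, b, sigma, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(5.0, 9.0, size=n)
    y = alpha + b * x + rng.normal(0, sigma, size=n)
    return ab.LogRegressionData(x, y)


class TestGibbsSampler:
    def test_tight_prior_dominates_data(self, stem_data):
        """An (almost) point-mass prior pins the posterior at its mean."""
        prior = ab.PriorSpec(mu=np.array([-4.0, 0.9]),
                             Sigma=np.diag([1e-12, 1e-12]))
        d = ab.gibbs_sample(stem_data, prior,
                            McmcConfig(n_iter=3000, burn_in=500, thin=1, seed=1))
        assert np.mean(d.alpha) == pytest.approx(-4.0, abs=1e-3)
        assert np.mean(d.b) == pytest.approx(0.9, abs=1e-3)

    def test_recovers_truth_noninformative(self):
        data = make_data(200, alpha=-3.0, b=0.85, sigma=0.1, seed=42)
        d = ab.gibbs_sample(data, ab.noninformative_prior(),
                            McmcConfig(n_iter=8000, burn_in=2000, thin=1, seed=2))
        for chain, truth in ((d.alpha, -3.0), (d.b, 0.85)):
            assert abs(np.mean(chain) - truth) < 3 * np.std(chain)
        assert np.all(d.sigma2 > 0)

    def test_fixed_sigma2_matches_conjugate_posterior(self, stem_data):
        """With sigma^2 known the draws are iid from the closed-form
        normal posterior; empirical moments must match it."""
        prior = ab.noninformative_prior()
        sig2 = 0.04
        mean, cov = ab.conjugate_posterior(stem_data, prior, sig2)
        d = ab.gibbs_sample(stem_data, prior,
                            McmcConfig(n_iter=50_000, burn_in=0, thin=1, seed=3),
                            fixed_sigma2=sig2)
        emp_mean = np.array([d.alpha.mean(), d.b.mean()])
        emp_cov = np.cov(np.vstack([d.alpha, d.b]))
        assert emp_mean == pytest.approx(mean, abs=0.01)
        assert np.max(np.abs((emp_cov - cov) / cov)) < 0.05
        assert np.all(d.sigma2 == sig2)

    def test_bitwise_reproducible(self, stem_data, short_mcmc):
        d1 = ab.gibbs_sample(stem_data, ab.noninformative_prior(), short_mcmc)
        d2 = ab.gibbs_sample(stem_data, ab.noninformative_prior(), short_mcmc)
        assert np.array_equal(d1.alpha, d2.alpha)
        assert np.array_equal(d1.b, d2.b)
        assert np.array_equal(d1.sigma2, d2.sigma2)

    def test_chain_length_bookkeeping(self, stem_data):
        cfg = McmcConfig(n_iter=1000, burn_in=400, thin=3, seed=5)
        d = ab.gibbs_sample(stem_data, ab.noninformative_prior(), cfg)
        assert len(d) == cfg.n_kept == 200

    def test_prior_precision_ladder_shrinks_toward_prior_mean(self, stem_data):
        """Posterior mean of b moves monotonically from the least-squares
        estimate toward the prior mean as prior precision grows."""
        b_ols = ab.ols_fit(stem_data).b_hat
        prior_mean_b = b_ols + 0.3
        dists = []
        for scale in (1e2, 1e-2, 1e-4, 1e-6):
            prior = ab.PriorSpec(
                mu=np.array([-4.0, prior_mean_b]),
                Sigma=np.diag([scale, scale]),
            )
            d = ab.gibbs_sample(
                stem_data, prior,
                McmcConfig(n_iter=6000, burn_in=1000, thin=1, seed=9),
            )
            dists.append(abs(np.mean(d.b) - prior_mean_b))
        assert dists == sorted(dists, reverse=True)

    def test_invalid_config_rejected(self):
        with pytest.raises(ab.GibbsError):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ab.GibbsError):
            McmcConfig(thin=0)


class TestSummarize:
    def test_constant_chain(self):
        c = np.full(50, 2.5)
        fs = summarize_chain(c, c, np.full(50, 1.0), component="stem")
        assert fs.alpha_hat == 2.5
        assert fs.alpha_interval == (2.5, 2.5)

    def test_quantile_convention_on_1_to_100(self):
        chain = np.arange(1.0, 101.0)
        fs = summarize_chain(chain, chain, np.ones(100), level=0.90)
        assert fs.b_interval[0] == pytest.approx(5.95)
        assert fs.b_interval[1] == pytest.approx(95.05)

    def test_monte_carlo_standard_normal(self, rng):
        z = rng.standard_normal(100_000)
        fs = summarize_chain(z, z, np.ones(z.size))
        assert abs(fs.b_hat) < 0.02
        assert fs.b_interval[0] == pytest.approx(-1.96, abs=0.05)
        assert fs.b_interval[1] == pytest.approx(1.96, abs=0.05)

    def test_bad_level_rejected(self, rng):
        z = rng.standard_normal(100)
        with pytest.raises(ValueError, match="level"):
            summarize_chain(z, z, np.ones(100), level=1.5)

    def test_method_label_follows_prior_kind(self, stem_data, short_mcmc):
        d = ab.gibbs_sample(stem_data, ab.noninformative_prior(), short_mcmc)
        assert ab.summarize(d, component="stem").method == "bayes_noninformative"


class TestDiagnostics:
    def _draws(self, alpha, b, sigma2, n=2000):
        cfg = McmcConfig(n_iter=n, burn_in=0, thin=1, seed=0)
        return ab.PosteriorDraws(alpha=alpha, b=b, sigma2=sigma2,
                                 config=cfg, prior=ab.noninformative_prior())

    def test_iid_chain_has_full_ess(self, rng):
        z = rng.standard_normal(2000)
        d = self._draws(z, rng.standard_normal(2000), np.abs(z) + 0.5)
        diag = ab.convergence_diagnostics(d)
        for name in ("alpha", "b"):
            assert diag.ess[name] > 0.9 * 2000
            assert abs(diag.geweke_z[name]) < 3

    def test_constant_chain_flagged_degenerate(self, rng):
        d = self._draws(np.ones(500), rng.standard_normal(500),
                        np.ones(500), n=500)
        diag = ab.convergence_diagnostics(d)
        assert "alpha" in diag.flagged and "sigma2" in diag.flagged
        assert not diag.ok

    def test_ar1_chain_ess_matches_theory(self, rng):
        """AR(1) with phi=0.5 has ESS/n = (1-phi)/(1+phi) = 1/3."""
        phi, n = 0.5, 100_000
        e = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = e[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + e[i]
        d = self._draws(x, rng.standard_normal(n),
                        np.ones(n) + 0.5 * np.abs(e), n=n)
        diag = ab.convergence_diagnostics(d)
        assert diag.ess["alpha"] / n == pytest.approx(1 / 3, rel=0.2)

    def test_short_chain_rejected(self, rng):
        z = rng.standard_normal(50)
        with pytest.raises(ab.GibbsError, match="too short"):
            ab.convergence_diagnostics(self._draws(z, z, np.abs(z) + 0.1, n=50))
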