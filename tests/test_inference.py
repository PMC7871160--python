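import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit, logit
from scipy.stats import binom, norm

import arviz as az
import prevapc as pv
from prevapc._hmc import DenseMass, DiagonalMass, sample_chain, slice_sample_1d
from prevapc.inference import SingleChainError


def make_samples(grid, spec, delta, alpha=None, beta=None, gamma=None, z=None,
                 sigma_z=None, chains=2):
    """Hand-built PosteriorSamples for post-processing tests."""
    delta = np.asarray(delta, dtype=float)
    S = len(delta)
    I, J, K = grid.I, grid.J, grid.K
    zeros = lambda *shape: np.zeros(shape)
    return pv.PosteriorSamples(
        spec=spec, grid=grid, seed=0, n_chains=chains,
        chain_ids=np.repeat(np.arange(chains), S // chains),
        delta=delta,
        alpha=alpha if alpha is not None else zeros(S, I),
        beta=beta if beta is not None else zeros(S, J),
        gamma=gamma if gamma is not None else zeros(S, K),
        z=z if z is not None else zeros(S, I, J),
        sigma_alpha=zeros(S), sigma_beta=zeros(S), sigma_gamma=zeros(S),
        sigma_z=sigma_z if sigma_z is not None else zeros(S),
    )


class TestHMCEngine:
    def test_recovers_correlated_gaussian(self):
        """HMC with a dense metric reproduces the moments of a strongly
        correlated 3-D Gaussian."""
        prec = np.linalg.inv(np.array([[1.0, 0.95, 0.0], [0.95, 1.0, 0.0], [0.0, 0.0, 4.0]]))
        mean = np.array([1.0, -2.0, 0.5])

        def logp_grad(x):
            d = x - mean
            g = -prec @ d
            return -0.5 * float(d @ prec @ d), g

        rng = np.random.default_rng(0)
        res = sample_chain(logp_grad, np.zeros(3), 300, 3000, rng, mass=DenseMass(prec))
        cov = np.linalg.inv(prec)
        np.testing.assert_allclose(res.draws.mean(axis=0), mean, atol=0.15)
        cov_err = np.abs(np.cov(res.draws.T) - cov)
        assert np.all(cov_err <= 0.1 + 0.1 * np.abs(cov))
        assert res.divergences == 0

    def test_diagonal_mass_adapts(self):
        """Badly scaled target: warmup variance adaptation fixes the metric."""
        scales = np.array([0.01, 1.0, 100.0])

        def logp_grad(x):
            return -0.5 * float(np.sum((x / scales) ** 2)), -x / scales**2

        rng = np.random.default_rng(1)
        res = sample_chain(logp_grad, np.zeros(3), 600, 2000, rng,
                           mass=DiagonalMass(np.ones(3)))
        np.testing.assert_allclose(res.draws.std(axis=0), scales, rtol=0.35)

    def test_slice_sampler_targets_normal(self):
        rng = np.random.default_rng(2)
        x, draws = 0.0, []
        logf = lambda t: -0.5 * (t - 3.0) ** 2
        for _ in range(4000):
            x = slice_sample_1d(logf, x, rng, width=1.0)
            draws.append(x)
        draws = np.asarray(draws[200:])
        assert draws.mean() == pytest.approx(3.0, abs=0.1)
        assert draws.std() == pytest.approx(1.0, abs=0.1)


@pytest.fixture(scope="module")
def single_cell():
    """y = 37 of n = 100 in one cell; intercept-only model."""
    table = pv.PrevalenceTable("cell", (20,), (2004,),
                               np.array([[37]]), np.array([[100]]))
    grid = pv.build_grid((20,), (2004,))
    spec = pv.APCModelSpec(include_period=False, include_cohort=False,
                           include_heterogeneity=False)
    fit = pv.sample_posterior(table, grid, spec, chains=4, iterations=1000,
                              warmup=500, seed=2)
    return table, grid, spec, fit


def exact_posterior(y=37, n=100, prior_sd=10.0):
    dens = lambda d: norm.pdf(d, 0, prior_sd) * binom.pmf(y, n, expit(d))
    Z, _ = quad(dens, -15, 15)
    return dens, Z


class TestSamplerCorrectness:
    def test_intercept_posterior_matches_quadrature(self, single_cell):
        """Posterior mean of the intercept agrees with 1-D numerical
        quadrature of the exact posterior within 3 Monte-Carlo SEs."""
        _, _, _, fit = single_cell
        dens, Z = exact_posterior()
        mean_q, _ = quad(lambda d: d * dens(d) / Z, -15, 15)
        ess = float(az.ess(az.from_dict(posterior={"d": fit.delta.reshape(4, -1)}))["d"])
        mcse = fit.delta.std() / np.sqrt(ess)
        assert abs(fit.delta.mean() - mean_q) < 3 * mcse

    def test_dic_matches_quadrature(self, single_cell):
        """DIC of the single-cell model agrees with the value computed by
        quadrature over the exact 1-D posterior."""
        table, grid, _, fit = single_cell
        dens, Z = exact_posterior()
        dev = lambda d: -2 * binom.logpmf(37, 100, expit(d))
        dbar_q, _ = quad(lambda d: dev(d) * dens(d) / Z, -15, 15)
        pbar_q, _ = quad(lambda d: expit(d) * dens(d) / Z, -15, 15)
        dic_q = 2 * dbar_q - dev(logit(pbar_q))
        dic = pv.compute_dic(fit, table, grid)
        assert dic.dic == pytest.approx(dic_q, abs=0.3)

    def test_same_seed_reproduces_draws(self, small_grid):
        truth = pv.generate_truth(small_grid, scenario="age_only", seed=4)
        table = pv.generate_table(truth)
        kw = dict(chains=2, iterations=60, warmup=60, seed=11)
        a = pv.sample_posterior(table, small_grid, pv.APCModelSpec.from_name("a"), **kw)
        b = pv.sample_posterior(table, small_grid, pv.APCModelSpec.from_name("a"), **kw)
        np.testing.assert_array_equal(a.delta, b.delta)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.sigma_z, b.sigma_z)

    def test_posterior_concentrates_with_huge_denominators(self):
        """Flat truth with n = 200,000 per cell: fitted prevalences land
        on the generating value."""
        grid = pv.build_grid(range(20, 40, 5), range(2004, 2013, 3))
        truth = pv.generate_truth(grid, scenario="null", effect_scale=0.0,
                                  heterogeneity_sd=0.0, seed=9,
                                  denominator=200_000)
        table = pv.generate_table(truth)
        fit = pv.sample_posterior(table, grid, pv.APCModelSpec(), chains=2,
                                  iterations=300, warmup=300, seed=4)
        p_mean = fit.cell_probability_draws().mean(axis=0)
        assert np.abs(p_mean - 0.35).max() < 0.005

    def test_draws_satisfy_sum_to_zero(self, apc_fit):
        for eff in (apc_fit.alpha, apc_fit.beta, apc_fit.gamma):
            assert np.abs(eff.sum(axis=1)).max() < 1e-10


class TestConvergenceChecking:
    def test_iid_chains_pass(self, study_grid):
        rng = np.random.default_rng(0)
        S = 2000
        samples = make_samples(study_grid, pv.APCModelSpec(),
                               delta=rng.normal(0, 1, S),
                               z=rng.normal(0, 1, (S, 12, 6)),
                               sigma_z=np.abs(rng.normal(0, 1, S)))
        samples.rhat.update({})
        report = pv.check_convergence(samples)
        assert report.passed
        assert report.max_rhat < 1.05

    def test_disjoint_chains_fail(self, study_grid):
        S = 400
        delta = np.concatenate([np.random.default_rng(1).normal(0, 0.1, S // 2),
                                10 + np.random.default_rng(2).normal(0, 0.1, S // 2)])
        samples = make_samples(study_grid, pv.APCModelSpec(), delta=delta,
                               sigma_z=np.ones(S))
        report = pv.check_convergence(samples)
        assert not report.passed
        assert dict(report.offenders)["delta"] > 1.05

    def test_infinite_threshold_always_passes(self, study_grid):
        S = 400
        delta = np.concatenate([np.zeros(S // 2), np.full(S // 2, 10.0)])
        samples = make_samples(study_grid, pv.APCModelSpec(), delta=delta,
                               sigma_z=np.ones(S))
        assert pv.check_convergence(samples, threshold=np.inf).passed

    def test_single_chain_is_an_error(self, study_grid):
        samples = make_samples(study_grid, pv.APCModelSpec(),
                               delta=np.zeros(10), chains=1)
        with pytest.raises(SingleChainError):
            pv.check_convergence(samples)


class TestDIC:
    def test_identical_draws_have_zero_pd(self):
        grid = pv.build_grid((20, 25), (2004, 2007))
        table = pv.PrevalenceTable("t", (20, 25), (2004, 2007),
                                   np.array([[3, 4], [5, 6]]),
                                   np.array([[10, 10], [10, 10]]))
        S = 40
        samples = make_samples(grid, pv.APCModelSpec(), delta=np.full(S, 0.2),
                               sigma_z=np.ones(S))
        dic = pv.compute_dic(samples, table, grid)
        assert dic.pd == pytest.approx(0.0, abs=1e-9)
        assert dic.dic == pytest.approx(dic.dbar, rel=1e-12)
        assert dic.dbar == pytest.approx(dic.dhat, rel=1e-12)

    def test_empty_draws_rejected(self, study_grid, full_table):
        samples = make_samples(study_grid, pv.APCModelSpec(), delta=np.zeros(0))
        with pytest.raises(ValueError):
            pv.compute_dic(samples, full_table, study_grid)

    def test_irrelevant_effect_inflates_pd(self, small_grid):
        """Adding the (irrelevant) cohort walk to fits of age-only data
        increases the effective parameter count on average."""
        pds = {"a": [], "ac": []}
        for r in range(4):
            truth = pv.generate_truth(small_grid, scenario="age_only",
                                      heterogeneity_sd=0.0, seed=50 + r)
            table = pv.generate_table(truth)
            for name in pds:
                fit = pv.sample_posterior(table, small_grid,
                                          pv.APCModelSpec.from_name(name),
                                          chains=2, iterations=200, warmup=200,
                                          seed=r)
                pds[name].append(pv.compute_dic(fit, table, small_grid).pd)
        assert np.mean(pds["ac"]) > np.mean(pds["a"])


class TestPersistence:
    def test_save_and_load_roundtrip(self, small_grid, tmp_path):
        truth = pv.generate_truth(small_grid, scenario="age_only", seed=4)
        table = pv.generate_table(truth, stratum_label="fit")
        fit = pv.sample_posterior(table, small_grid, pv.APCModelSpec(), chains=2,
                                  iterations=50, warmup=50, seed=11)
        pv.save_fit(fit, table, tmp_path / "fit")
        loaded, table2 = pv.load_fit(tmp_path / "fit")
        np.testing.assert_allclose(loaded.delta, fit.delta)
        np.testing.assert_allclose(loaded.gamma, fit.gamma, atol=1e-12)
        np.testing.assert_array_equal(table2.smokers, table.smokers)
        assert loaded.spec == fit.spec
        assert (tmp_path / "fit" / "run_metadata.txt").exists()
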