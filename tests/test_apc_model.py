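import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit
from scipy.stats import binom, halfnorm, norm

import prevapc as pv
from prevapc.apc_model import MODEL_NAMES, cell_probability


def random_params(grid, rng, sigma=0.5):
    def sz(v):
        return v - v.mean()

    return pv.APCParameters(
        delta=float(rng.normal()),
        alpha=sz(rng.normal(0, sigma, grid.I)),
        beta=sz(rng.normal(0, sigma, grid.J)),
        gamma=sz(rng.normal(0, sigma, grid.K)),
        z=rng.normal(0, 0.1, (grid.I, grid.J)),
        sigma_alpha=0.5, sigma_beta=0.5, sigma_gamma=0.5, sigma_z=0.1,
    )


@pytest.fixture(scope="module")
def grid32():
    return pv.build_grid((20, 25, 30), (2004, 2007))


class TestLinearPredictor:
    def test_all_zero_parameters_give_even_odds(self, grid32):
        p = pv.APCParameters(0.0, np.zeros(3), np.zeros(2), np.zeros(grid32.K),
                             np.zeros((3, 2)))
        np.testing.assert_array_equal(pv.linear_predictor(p, grid32), 0.0)
        np.testing.assert_array_equal(cell_probability(p, grid32), 0.5)

    def test_intercept_only_sets_constant_prevalence(self, grid32):
        p = pv.APCParameters(logit(0.3), np.zeros(3), np.zeros(2),
                             np.zeros(grid32.K), np.zeros((3, 2)))
        np.testing.assert_allclose(cell_probability(p, grid32), 0.3)

    @given(seed=st.integers(0, 10_000))
    def test_matches_cell_by_cell_oracle(self, grid32, seed):
        params = random_params(grid32, np.random.default_rng(seed))
        eta = pv.linear_predictor(params, grid32)
        for i in range(3):
            for j in range(2):
                k = grid32.cohort_of_cell(i + 1, j + 1)
                expected = (
                    params.delta + params.alpha[i] + params.beta[j]
                    + params.gamma[k - 1] + params.z[i, j]
                )
                assert eta[i, j] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, grid32):
        p = pv.APCParameters(0.0, np.zeros(4), np.zeros(2), np.zeros(grid32.K),
                             np.zeros((4, 2)))
        with pytest.raises(ValueError):
            pv.linear_predictor(p, grid32)


class TestLogLikelihood:
    def test_even_odds_closed_form(self, grid32):
        rng = np.random.default_rng(0)
        n = rng.integers(5, 40, size=(3, 2))
        y = rng.integers(0, n + 1)
        table = pv.PrevalenceTable("t", (20, 25, 30), (2004, 2007), y, n)
        p = pv.APCParameters(0.0, np.zeros(3), np.zeros(2), np.zeros(grid32.K),
                             np.zeros((3, 2)))
        from scipy.special import gammaln

        expected = float(
            np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1) - n * np.log(2))
        )
        assert pv.log_likelihood(p, table, grid32) == pytest.approx(expected, rel=1e-12)

    def test_saturated_cell_limit(self):
        grid = pv.build_grid((20,), (2004,))
        table = pv.PrevalenceTable("t", (20,), (2004,), np.array([[50]]), np.array([[50]]))
        p = pv.APCParameters(30.0, np.zeros(1), np.zeros(1), np.zeros(1), np.zeros((1, 1)))
        assert pv.log_likelihood(p, table, grid) == pytest.approx(0.0, abs=1e-8)

    @given(seed=st.integers(0, 10_000))
    def test_matches_scipy_cell_loop(self, grid32, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60, size=(3, 2))
        y = rng.integers(0, n + 1)
        table = pv.PrevalenceTable("t", (20, 25, 30), (2004, 2007), y, n)
        params = random_params(grid32, rng)
        probs = cell_probability(params, grid32)
        expected = sum(
            binom.logpmf(y[i, j], n[i, j], probs[i, j])
            for i in range(3) for j in range(2)
        )
        assert pv.log_likelihood(params, table, grid32) == pytest.approx(expected, rel=1e-9)


class TestLogPrior:
    def test_four_level_effect_matches_normal_densities(self):
        grid = pv.build_grid((20, 25, 30, 35), (2004,))
        alpha = np.array([0.3, -0.1, 0.2, -0.4])
        p = pv.APCParameters(
            0.5, alpha, np.zeros(1), np.zeros(grid.K), np.zeros((4, 1)),
            sigma_alpha=0.7,
        )
        spec = pv.APCModelSpec(include_period=False, include_cohort=False,
                               include_heterogeneity=False)
        expected = (
            norm.logpdf(0.5, scale=10.0)
            + norm.logpdf(np.diff(alpha), scale=0.7).sum()
            + halfnorm.logpdf(0.7, scale=1.0)
        )
        assert pv.log_prior(p, spec) == pytest.approx(expected, rel=1e-12)

    def test_excluded_effect_contributes_nothing(self):
        grid = pv.build_grid((20, 25, 30), (2004, 2007, 2010))
        rng = np.random.default_rng(1)
        base = random_params(grid, rng)
        no_cohort = pv.APCParameters(
            base.delta, base.alpha, base.beta, np.zeros(grid.K), base.z,
            sigma_alpha=base.sigma_alpha, sigma_beta=base.sigma_beta,
            sigma_gamma=0.0, sigma_z=base.sigma_z,
        )
        spec_ap = pv.APCModelSpec(include_cohort=False)
        spec_apc = pv.APCModelSpec()
        with_cohort = pv.APCParameters(
            base.delta, base.alpha, base.beta, np.zeros(grid.K), base.z,
            sigma_alpha=base.sigma_alpha, sigma_beta=base.sigma_beta,
            sigma_gamma=0.5, sigma_z=base.sigma_z,
        )
        # age-period prior = full prior minus the (flat-at-zero) cohort walk
        # terms and its hyperprior
        diff = pv.log_prior(with_cohort, spec_apc) - pv.log_prior(no_cohort, spec_ap)
        expected_cohort_terms = (
            norm.logpdf(np.zeros(grid.K - 1), scale=0.5).sum()
            + halfnorm.logpdf(0.5, scale=1.0)
        )
        assert diff == pytest.approx(expected_cohort_terms, rel=1e-12)

    def test_constant_vector_maximizes_rw1_term(self):
        grid = pv.build_grid((20, 25, 30, 35), (2004,))
        spec = pv.APCModelSpec(include_period=False, include_cohort=False,
                               include_heterogeneity=False)

        def lp(alpha):
            p = pv.APCParameters(0.0, alpha, np.zeros(1), np.zeros(grid.K),
                                 np.zeros((4, 1)), sigma_alpha=0.3)
            return pv.log_prior(p, spec)

        flat = lp(np.zeros(4))
        rng = np.random.default_rng(2)
        for _ in range(20):
            wiggly = rng.normal(0, 0.2, 4)
            wiggly -= wiggly.mean()
            assert lp(wiggly) <= flat + 1e-12

    def test_non_positive_sigma_rejected(self):
        grid = pv.build_grid((20, 25), (2004, 2007))
        p = pv.APCParameters(0.0, np.array([0.1, -0.1]), np.zeros(2),
                             np.zeros(grid.K), np.zeros((2, 2)),
                             sigma_alpha=0.0, sigma_beta=1.0, sigma_gamma=1.0,
                             sigma_z=1.0)
        with pytest.raises(ValueError):
            pv.log_prior(p, pv.APCModelSpec())


class TestCenterEffects:
    def test_uniform_effect_moves_into_intercept(self):
        grid = pv.build_grid((20, 25, 30), (2004,))
        p = pv.APCParameters(0.0, np.ones(3), np.zeros(1), np.zeros(grid.K),
                             np.zeros((3, 1)))
        c = pv.center_effects(p)
        np.testing.assert_array_equal(c.alpha, 0.0)
        assert c.delta == pytest.approx(1.0)

    def test_idempotent(self):
        grid = pv.build_grid((20, 25, 30), (2004, 2007))
        p = random_params(grid, np.random.default_rng(5))
        once = pv.center_effects(p)
        twice = pv.center_effects(once)
        assert once.delta == twice.delta
        np.testing.assert_array_equal(once.alpha, twice.alpha)

    @given(seed=st.integers(0, 10_000))
    def test_linear_predictor_invariant(self, seed):
        grid = pv.build_grid((20, 25, 30), (2004, 2007))
        rng = np.random.default_rng(seed)
        p = pv.APCParameters(
            float(rng.normal()), rng.normal(0, 1, 3), rng.normal(0, 1, 2),
            rng.normal(0, 1, grid.K), rng.normal(0, 1, (3, 2)),
        )
        eta_before = pv.linear_predictor(p, grid)
        centered = pv.center_effects(p)
        eta_after = pv.linear_predictor(centered, grid)
        assert np.abs(eta_after - eta_before).max() < 1e-12
        for eff in (centered.alpha, centered.beta, centered.gamma):
            assert abs(eff.sum()) < 1e-10


class TestModelFamily:
    def test_submodel_names(self):
        assert set(MODEL_NAMES) == {"a", "ap", "ac", "apc"}
        assert pv.APCModelSpec.from_name("ac").include_cohort
        assert not pv.APCModelSpec.from_name("ac").include_period
        assert pv.APCModelSpec.from_name("apc").name == "apc"
        with pytest.raises(ValueError):
            pv.APCModelSpec.from_name("pc")

    def test_submodels_nest_by_zeroing_effects(self, grid32):
        """Fixing gamma = 0 in the full model reproduces the age-period
        linear predictor, etc."""
        rng = np.random.default_rng(7)
        full = random_params(grid32, rng)
        ap = pv.APCParameters(full.delta, full.alpha, full.beta,
                              np.zeros(grid32.K), full.z)
        gamma_zeroed = pv.APCParameters(full.delta, full.alpha, full.beta,
                                        np.zeros(grid32.K), full.z)
        np.testing.assert_array_equal(
            pv.linear_predictor(ap, grid32), pv.linear_predictor(gamma_zeroed, grid32)
        )
        a_only = pv.APCParameters(full.delta, full.alpha, np.zeros(grid32.J),
                                  np.zeros(grid32.K), full.z)
        eta = pv.linear_predictor(a_only, grid32)
        assert np.allclose(np.diff(eta - full.z, axis=1), 0.0)

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = pv.APCModelSpec(include_period=False, prior_scale_effects=2.5)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert pv.APCModelSpec.from_yaml(path) == spec

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            pv.APCModelSpec(prior_scale_effects=0.0)

    def test_expit_logit_inverse(self):
        p = np.linspace(0.01, 0.99, 23)
        np.testing.assert_allclose(expit(logit(p)), p, atol=1e-15)
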