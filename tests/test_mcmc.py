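"""The MCMC engine: likelihood, variance updates, and the block sampler."""

import numpy as np
import pytest

import morbmap as m
from morbmap.mcmc import load_chains, save_chains


def loglik_oracle(categories, eta):
    """Naive unstabilised evaluation of the multinomial-logit likelihood."""
    total = 0.0
    for i, k in enumerate(categories):
        denom = 1.0 + sum(np.exp(eta[i, j]) for j in range(7))
        p = (1.0 if k == 0 else np.exp(eta[i, k - 1])) / denom
        total += np.log(p)
    return total


class TestLogLikelihood:
    def test_symmetric_null(self):
        """One child, all eta = 0: probability 1/8 for any category."""
        for k in range(8):
            assert m.log_likelihood([k], np.zeros((1, 7))) == pytest.approx(np.log(1 / 8))

    def test_single_nonzero_closed_form(self):
        eta = np.zeros((1, 7))
        eta[0, 6] = 2.0  # category 7
        assert m.log_likelihood([7], eta) == pytest.approx(np.log(np.e**2 / (7 + np.e**2)))

    def test_matches_unstabilised_oracle(self, rng):
        eta = rng.normal(0, 2, size=(30, 7))
        y = rng.integers(0, 8, size=30)
        assert m.log_likelihood(y, eta) == pytest.approx(loglik_oracle(y, eta), abs=1e-10)

    def test_rejects_non_finite(self):
        eta = np.zeros((2, 7))
        eta[0, 0] = np.inf
        with pytest.raises(ValueError, match="NaN or inf"):
            m.log_likelihood([0, 0], eta)


class TestBlockVariance:
    def test_inverse_gamma_mean_at_zero_coefficients(self, rng):
        """coef = 0: draws are IG(a + rank/2, b); empirical mean over 100k
        draws matches b/(a + rank/2 - 1) within 3 MCSE."""
        a, b = 1.0, 2.0
        penalty = np.eye(4)  # rank 4 -> shape 3, variance exists
        draws = np.array(
            [m.sample_block_variance(np.zeros(4), penalty, a, b, rng) for _ in range(100_000)]
        )
        shape = a + 2.0
        mean = b / (shape - 1)
        sd = np.sqrt(b**2 / ((shape - 1) ** 2 * (shape - 2)))
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(100_000)

    def test_rank_zero_penalty_rejected(self, rng):
        with pytest.raises(ValueError, match="rank-0"):
            m.sample_block_variance(np.zeros(3), np.zeros((3, 3)), 1.0, 1.0, rng)

    def test_non_psd_penalty_rejected(self, rng):
        with pytest.raises(ValueError, match="positive semidefinite"):
            m.sample_block_variance(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]), 1, 1, rng)

    def test_seed_reproducibility(self):
        r1 = np.random.default_rng(7)
        r2 = np.random.default_rng(7)
        d1 = [m.sample_block_variance(np.ones(3), np.eye(3), 0.5, 0.5, r1) for _ in range(5)]
        d2 = [m.sample_block_variance(np.ones(3), np.eye(3), 0.5, 0.5, r2) for _ in range(5)]
        assert d1 == d2


class TestModelSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            m.ModelSpec(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            m.ModelSpec(thinning=0)
        with pytest.raises(ValueError):
            m.ModelSpec(ig_a=0)


@pytest.fixture(scope="module")
def fitted(small_survey):
    spec = m.ModelSpec(n_iterations=600, burn_in=200, thinning=2, seed=77)
    post = m.run_mcmc(small_survey.design, small_survey.records["category"].to_numpy(), spec)
    return post


class TestRunMCMC:
    def test_determinism(self, small_survey, fitted):
        spec = m.ModelSpec(n_iterations=600, burn_in=200, thinning=2, seed=77)
        again = m.run_mcmc(small_survey.design, small_survey.records["category"].to_numpy(), spec)
        for k in fitted.categories:
            for name, arr in fitted.categories[k].items():
                assert np.array_equal(arr, again.categories[k][name]), (k, name)

    def test_theta_draws_sum_to_zero(self, fitted):
        for k in fitted.categories:
            assert np.abs(fitted.categories[k]["theta"].sum(axis=1)).max() < 1e-8

    def test_variance_draws_positive(self, fitted):
        for k in fitted.categories:
            assert (fitted.categories[k]["sigma2_theta"] > 0).all()
            assert (fitted.categories[k]["sigma2_phi"] > 0).all()

    def test_draw_count_and_shapes(self, fitted, small_survey):
        assert fitted.n_draws == 200
        assert fitted.categories[1]["beta"].shape == (200, small_survey.design.p)
        assert fitted.categories[1]["theta"].shape == (200, 27)

    def test_prior_precision_shrinks_posterior(self, small_survey):
        """Monotone shrinkage: a much tighter fixed-effect prior pulls the
        posterior mean of every non-intercept coefficient toward zero."""
        y = small_survey.records["category"].to_numpy()
        loose = m.run_mcmc(
            small_survey.design, y,
            m.ModelSpec(n_iterations=400, burn_in=100, thinning=1, seed=5,
                        include_spatial=False, include_unstructured=False),
        )
        tight = m.run_mcmc(
            small_survey.design, y,
            m.ModelSpec(n_iterations=400, burn_in=100, thinning=1, seed=5,
                        beta_prior_precision=1e4,
                        include_spatial=False, include_unstructured=False),
        )
        for k in range(1, 8):
            lo = np.abs(loose.categories[k]["beta"].mean(0)[1:])
            ti = np.abs(tight.categories[k]["beta"].mean(0)[1:])
            # prior sd 0.01 pins the posterior near zero
            assert ti.max() < 0.1
            assert (ti <= lo + 0.05).all()

    def test_misaligned_inputs_rejected(self, small_survey):
        with pytest.raises(ValueError, match="aligned"):
            m.run_mcmc(small_survey.design, [0, 1], m.ModelSpec())

    def test_chain_persistence_round_trip(self, fitted, tmp_path):
        save_chains(fitted, tmp_path / "chains")
        loaded = load_chains(tmp_path / "chains")
        assert loaded.columns == fitted.columns
        for k in fitted.categories:
            for name, arr in fitted.categories[k].items():
                assert np.allclose(arr, loaded.categories[k][name], atol=1e-9), (k, name)


class TestAgainstIndependentOptimiser:
    def test_posterior_mean_matches_multinomial_mle(self):
        """No spatial terms, diffuse priors: the posterior mean of beta on a
        large synthetic dataset agrees with the maximum-likelihood
        multinomial-logit fit from an independent optimiser (scikit-learn)
        within 2 posterior SD."""
        from sklearn.linear_model import LogisticRegression

        truth = m.two_binary_truth(seed=11, n_children=4000,
                                   spatial_var=0.0, unstructured_var=0.0)
        survey = m.generate_survey(truth)
        y = survey.records["category"].to_numpy()
        post = m.run_mcmc(
            survey.design, y,
            m.ModelSpec(n_iterations=2000, burn_in=500, thinning=2, seed=3,
                        include_spatial=False, include_unstructured=False),
        )
        mle = LogisticRegression(C=1e6, max_iter=2000).fit(survey.design.Z[:, 1:], y)
        for k in range(1, 8):
            chain = post.categories[k]["beta"]
            mean, sd = chain.mean(0), chain.std(0)
            ref = np.concatenate(
                [[mle.intercept_[k] - mle.intercept_[0]], mle.coef_[k] - mle.coef_[0]]
            )
            assert (np.abs(mean - ref) < 2 * sd).all(), k

    def test_seed_stability_of_posterior_means(self, small_survey):
        """Two independent chains agree on every posterior mean within 3
        combined Monte-Carlo standard errors (ESS-based)."""
        import arviz as az

        y = small_survey.records["category"].to_numpy()
        spec1 = m.ModelSpec(n_iterations=2000, burn_in=500, thinning=1, seed=21)
        spec2 = m.ModelSpec(n_iterations=2000, burn_in=500, thinning=1, seed=22)
        p1 = m.run_mcmc(small_survey.design, y, spec1)
        p2 = m.run_mcmc(small_survey.design, y, spec2)
        for k in (1, 4, 7):
            b1, b2 = p1.categories[k]["beta"], p2.categories[k]["beta"]
            for j in range(b1.shape[1]):
                mc1 = b1[:, j].std() / np.sqrt(max(az.ess(b1[:, j][None, :]), 1.0))
                mc2 = b2[:, j].std() / np.sqrt(max(az.ess(b2[:, j][None, :]), 1.0))
                tol = 3 * np.hypot(mc1, mc2)
                assert abs(b1[:, j].mean() - b2[:, j].mean()) < max(tol, 0.02), (k, j)
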