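import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmvae.io import MISSING
from bmvae.genotype import (
    GibbsGenotyper,
    genotype_posterior,
    gibbs_infer,
    update_error_rates,
)


def brute_force_posterior(values, labels, alpha, beta):
    """Direct per-entry evaluation of the genotype posterior (oracle)."""
    k = labels.max() + 1
    n, m = values.shape
    post = np.zeros((k, m))
    for kk in range(k):
        for j in range(m):
            p1 = p0 = 1.0
            for i in range(n):
                if labels[i] != kk or values[i, j] == MISSING:
                    continue
                if values[i, j] == 1:
                    p1 *= 1 - beta
                    p0 *= alpha
                else:
                    p1 *= beta
                    p0 *= 1 - alpha
            post[kk, j] = p1 / (p1 + p0)
    return post


def bernoulli_loglik(values, e_cells, alpha, beta):
    obs = values != MISSING
    ll = 0.0
    p = np.where(
        e_cells == 1,
        np.where(values == 1, 1 - beta, beta),
        np.where(values == 1, alpha, 1 - alpha),
    )
    return np.log(np.clip(p[obs], 1e-300, None)).sum()


class TestGenotypePosterior:
    def test_single_positive_cell(self):
        post = genotype_posterior(np.array([[1]]), [0], alpha=0.01, beta=0.01)
        assert post[0, 0] == pytest.approx(0.99 / (0.99 + 0.01))

    def test_two_negative_cells(self):
        post = genotype_posterior(np.array([[0], [0]]), [0, 0], alpha=0.01, beta=0.3)
        assert post[0, 0] == pytest.approx(0.09 / (0.09 + 0.9801))

    def test_all_missing_gives_uniform(self):
        values = np.array([[MISSING, 1], [MISSING, 0]])
        post = genotype_posterior(values, [0, 0], alpha=0.01, beta=0.3)
        assert post[0, 0] == 0.5

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            genotype_posterior(np.array([[1], [0]]), [0, 2], alpha=0.1, beta=0.1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_and_normalizes(self, seed):
        r = np.random.default_rng(seed)
        n, m, k = 12, 6, 3
        values = r.integers(0, 2, size=(n, m)).astype(np.int8)
        values[r.random((n, m)) < 0.2] = MISSING
        labels = np.concatenate([np.arange(k), r.integers(0, k, size=n - k)])
        alpha, beta = r.uniform(0.01, 0.3), r.uniform(0.05, 0.6)
        post = genotype_posterior(values, labels, alpha, beta)
        oracle = brute_force_posterior(values, labels, alpha, beta)
        np.testing.assert_allclose(post, oracle, rtol=1e-9, atol=1e-12)
        # complementary state posterior sums to one by the same oracle
        np.testing.assert_allclose(post + (1 - oracle), 1.0)


class TestUpdateErrorRates:
    def test_noiseless_identity(self):
        e = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)
        labels = np.array([0, 0, 1])
        values = e[labels]
        assert update_error_rates(values, e, labels) == (0.0, 0.0)

    def test_single_row_alpha(self):
        values = np.array([[1, 0, 0, 0]])
        e = np.zeros((1, 4), dtype=np.int8)
        alpha, beta = update_error_rates(values, e, [0], beta_fallback=0.123)
        assert alpha == pytest.approx(0.25)
        assert beta == pytest.approx(0.123)  # no genotype-1 positions

    def test_missing_entries_excluded(self):
        values = np.array([[1, MISSING], [MISSING, 0]])
        e = np.array([[0, 1]], dtype=np.int8)
        alpha, beta = update_error_rates(values, e, [0, 0])
        assert alpha == 1.0  # one observed genotype-0 entry, read as 1
        assert beta == 1.0  # one observed genotype-1 entry, read as 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_is_likelihood_maximizer(self, seed):
        # closed-form updates agree with a grid search of the Bernoulli
        # log-likelihood over (alpha, beta) at 1e-3 resolution
        r = np.random.default_rng(seed)
        n, m, k = 50, 20, 3
        labels = np.concatenate([np.arange(k), r.integers(0, k, size=n - k)])
        e = r.integers(0, 2, size=(k, m)).astype(np.int8)
        values = e[labels].copy()
        flip = r.random((n, m))
        values[(values == 1) & (flip < 0.3)] = 0
        values[(e[labels] == 0) & (flip < 0.05)] = 1
        values[r.random((n, m)) < 0.1] = MISSING
        alpha, beta = update_error_rates(values, e, labels, 0.5, 0.5)

        grid = np.arange(1e-3, 1.0, 1e-3)
        e_cells = e[labels]
        obs = values != MISSING
        n10 = ((values == 1) & (e_cells == 0) & obs).sum()
        n00 = ((values == 0) & (e_cells == 0) & obs).sum()
        n01 = ((values == 0) & (e_cells == 1) & obs).sum()
        n11 = ((values == 1) & (e_cells == 1) & obs).sum()
        ll_a = n10 * np.log(grid) + n00 * np.log1p(-grid)
        ll_b = n01 * np.log(grid) + n11 * np.log1p(-grid)
        assert abs(alpha - grid[np.argmax(ll_a)]) <= 1e-3
        assert abs(beta - grid[np.argmax(ll_b)]) <= 1e-3

    def test_monotone_in_false_positives(self, rng):
        e = np.zeros((1, 30), dtype=np.int8)
        labels = np.zeros(10, dtype=int)
        values = np.zeros((10, 30), dtype=np.int8)
        alphas = []
        for n_fp in (0, 5, 20, 60):
            v = values.copy()
            flat = rng.choice(300, size=n_fp, replace=False)
            v[np.unravel_index(flat, v.shape)] = 1
            alphas.append(update_error_rates(v, e, labels, 0.0, 0.0)[0])
        assert alphas == sorted(alphas)


class TestGibbsInfer:
    def test_noiseless_recovery(self):
        e = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        labels = np.array([0, 0, 0, 1, 1, 1])
        values = e[labels]
        result = gibbs_infer(values, labels, seed=0)
        np.testing.assert_array_equal(result.genotypes, e)
        assert result.alpha <= 1e-5 and result.beta <= 1e-5
        assert result.converged

    def test_reproducible_given_seed(self, noisy_small_dataset):
        ds = noisy_small_dataset
        r1 = gibbs_infer(ds.observed, ds.true_labels, seed=9)
        r2 = gibbs_infer(ds.observed, ds.true_labels, seed=9)
        np.testing.assert_array_equal(r1.genotypes, r2.genotypes)
        assert (r1.alpha, r1.beta) == (r2.alpha, r2.beta)

    def test_error_rate_recovery_with_true_labels(self, noisy_small_dataset):
        # with ground-truth labels the false-negative rate estimate lands
        # near the simulated beta; alpha is biased upward by doublet cells
        # (their second clone's mutations read as false positives)
        ds = noisy_small_dataset
        result = gibbs_infer(ds.observed, ds.true_labels, seed=4)
        assert result.beta == pytest.approx(ds.config.beta, abs=0.05)
        assert ds.config.alpha <= result.alpha <= ds.config.alpha + 0.05

    def test_rate_recovery_without_doublets(self):
        from bmvae.simulate import SimulationConfig, simulate_dataset

        ds = simulate_dataset(SimulationConfig(
            alpha=0.01, beta=0.3, n_cells=300, n_loci=120, n_clones=4,
            doublet_rate=0.0, seed=13,
        ))
        result = gibbs_infer(ds.observed, ds.true_labels, seed=4)
        assert result.alpha == pytest.approx(0.01, abs=0.01)
        assert result.beta == pytest.approx(0.3, abs=0.05)

    def test_genotype_is_thresholded_posterior(self, noisy_small_dataset):
        ds = noisy_small_dataset
        result = gibbs_infer(ds.observed, ds.true_labels, seed=4)
        np.testing.assert_array_equal(result.genotypes, result.posterior > 0.5)

    def test_estimator_get_set_params(self):
        est = GibbsGenotyper()
        est.set_params(max_iter=13, tol=1e-3)
        assert est.get_params()["max_iter"] == 13
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
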