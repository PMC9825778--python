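import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmvae.io import MISSING, MutationMatrix
from bmvae.vae import BinaryMutationVAE, embed, kl_term, reconstruction_loss


class TestReconstructionLoss:
    def test_symmetric_half(self):
        assert reconstruction_loss([1, 0], [0.5, 0.5]) == pytest.approx(2 * np.log(2))

    def test_missing_locus_excluded(self):
        assert reconstruction_loss([1, MISSING], [0.5, 0.9]) == pytest.approx(np.log(2))

    def test_perfect_reconstruction_near_zero(self):
        loss = reconstruction_loss([1, 0, 1], [0.999999, 0.000001, 0.999999])
        assert loss <= 1e-5

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            reconstruction_loss([1, 0], [0.5])

    def test_all_missing_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert reconstruction_loss([MISSING, MISSING], [0.3, 0.7]) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_masking_invariance(self, seed):
        # the reconstruction probability stored at a missing locus never
        # affects the loss
        r = np.random.default_rng(seed)
        x = r.integers(0, 2, size=20)
        x[r.random(20) < 0.4] = MISSING
        if not (x != MISSING).any():
            x[0] = 1
        xhat = r.uniform(0.01, 0.99, size=20)
        base = reconstruction_loss(x, xhat)
        xhat2 = xhat.copy()
        xhat2[x == MISSING] = r.uniform(0.01, 0.99, size=(x == MISSING).sum())
        assert reconstruction_loss(x, xhat2) == base


class TestKLTerm:
    def test_prior_equals_posterior(self):
        assert kl_term([0, 0, 0], [1, 1, 1]) == 0.0

    def test_unit_mean_shift(self):
        assert kl_term([1.0], [1.0]) == pytest.approx(0.5)

    def test_wide_posterior(self):
        assert kl_term([0.0], [2.0]) == pytest.approx(0.5 * (4 - 1 - np.log(4)))

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="positive"):
            kl_term([0.0], [0.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_matches_monte_carlo_divergence(self, seed):
        # closed form agrees with a Monte-Carlo estimate of
        # E_q[log q(z) - log p(z)] within 3 standard errors
        r = np.random.default_rng(seed)
        d = 3
        mu = r.normal(0, 1.5, size=d)
        sigma = r.uniform(0.3, 2.0, size=d)
        n = 40_000
        z = mu + sigma * r.standard_normal((n, d))
        log_q = -0.5 * (((z - mu) / sigma) ** 2 + np.log(2 * np.pi) + 2 * np.log(sigma)).sum(1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(1)
        samples = log_q - log_p
        se = samples.std(ddof=1) / np.sqrt(n)
        assert abs(kl_term(mu, sigma) - samples.mean()) < 3 * se + 1e-9


class TestTraining:
    def test_same_seed_identical_history(self, noisy_small_dataset):
        ds = noisy_small_dataset
        kw = dict(epochs=20, random_state=7)
        h1 = BinaryMutationVAE(**kw).fit(ds.observed).loss_history_
        h2 = BinaryMutationVAE(**kw).fit(ds.observed).loss_history_
        assert h1 == h2

    def test_loss_improves(self, noisy_small_dataset):
        m = BinaryMutationVAE(epochs=100, random_state=3).fit(
            noisy_small_dataset.observed
        )
        assert min(m.loss_history_) <= m.loss_history_[0]
        assert len(m.loss_history_) == 100

    def test_zero_kl_weight_contributes_nothing(self, noisy_small_dataset):
        m = BinaryMutationVAE(epochs=5, kl_weight=0.0, random_state=3).fit(
            noisy_small_dataset.observed
        )
        assert all(v == 0.0 for v in m.kl_loss_history_)

    def test_default_architecture_from_m(self, noisy_small_dataset):
        m = BinaryMutationVAE(epochs=2, random_state=0).fit(noisy_small_dataset.observed)
        n_loci = noisy_small_dataset.observed.n_loci
        assert m.params_["W1"].shape == (n_loci, n_loci // 5)
        assert m.params_["W2"].shape == (n_loci // 5, n_loci // 10)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BinaryMutationVAE(latent_dim=0).fit(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            BinaryMutationVAE(learning_rate=0).fit(np.zeros((4, 4)))


class TestEmbedding:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted(noisy_small_dataset):
        return BinaryMutationVAE(epochs=40, random_state=5).fit(
            noisy_small_dataset.observed
        )

    def test_shape_is_n_by_latent_dim(self, fitted, noisy_small_dataset):
        z = fitted.transform(noisy_small_dataset.observed)
        assert z.shape == (noisy_small_dataset.observed.n_cells, 3)
        assert np.isfinite(z).all()

    def test_deterministic_and_idempotent(self, fitted, noisy_small_dataset):
        z1 = fitted.transform(noisy_small_dataset.observed)
        z2 = fitted.transform(noisy_small_dataset.observed)
        np.testing.assert_array_equal(z1, z2)

    def test_identical_cells_identical_rows(self, fitted, noisy_small_dataset):
        row = noisy_small_dataset.observed.values[0]
        twin = MutationMatrix(np.vstack([row, row]))
        z = fitted.transform(twin)
        np.testing.assert_array_equal(z[0], z[1])

    def test_locus_count_mismatch_rejected(self, fitted):
        with pytest.raises(ValueError, match="loci"):
            fitted.transform(np.zeros((3, 7)))

    def test_embed_wrapper_keeps_cell_ids(self, fitted, noisy_small_dataset):
        emb = embed(noisy_small_dataset.observed, fitted)
        assert emb.cell_ids == noisy_small_dataset.observed.cell_ids

    def test_missing_encoded_as_zero(self, fitted, noisy_small_dataset):
        # a missing entry enters the encoder exactly like an observed 0
        row = noisy_small_dataset.observed.values[0].copy()
        row[0] = MISSING
        as_missing = fitted.transform(row[None, :])
        row[0] = 0
        as_zero = fitted.transform(row[None, :])
        np.testing.assert_array_equal(as_missing, as_zero)
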