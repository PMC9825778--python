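"""Variational autoencoder for binary single-cell mutation profiles.

Each cell's M-locus profile ``x`` (entries 0/1, missing allowed) is mapped
by a fully connected encoder to a diagonal Gaussian posterior
``q(z|x) = N(mu_z, diag(sigma_z^2))`` over a low-dimensional latent space;
a mirrored decoder maps ``z`` back to per-locus Bernoulli probabilities.
Training minimizes, per batch mean over cells,

    lambda * KL(q(z|x) || N(0, I))  +  sum_j BCE(x_j, xhat_j)

where the binary cross-entropy sum runs over observed loci only: missing
entries are fed to the encoder as 0 but contribute nothing to the loss.
Optimization uses RMSprop with the reparameterization trick
``z = mu + sigma * eps``.  After training, a cell's latent representation
is the posterior mean ``mu_z`` (no sampling).

The network is implemented directly on NumPy arrays with hand-written
backpropagation; for matrices of a few thousand cells and loci this runs
comfortably on a single CPU core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from bmvae.io import MISSING, MutationMatrix

_EPS = 1e-7  # probability clamp inside the loss, avoids log(0)
_LEAKY_SLOPE = 0.01
_RMS_DECAY = 0.99
_RMS_EPS = 1e-8


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class LatentEmbedding:
    """Posterior-mean latent coordinates, one row per cell."""

    coords: np.ndarray  # (N, D) float
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        if not np.isfinite(self.coords).all():
            raise ValueError("latent coordinates must be finite")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.coords.shape[0])]
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("one cell_id per row required")


def reconstruction_loss(x: np.ndarray, xhat: np.ndarray) -> float:
    """Masked Bernoulli cross-entropy of one cell, summed over observed loci.

    ``x`` holds 0/1 observations with :data:`~bmvae.io.MISSING` marking
    unobserved loci, which are excluded from the sum.  ``xhat`` holds
    reconstruction probabilities, clamped to ``[1e-7, 1 - 1e-7]``.
    """
    x = np.asarray(x)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"length mismatch: x has {x.shape}, xhat has {xhat.shape}")
    mask = x != MISSING
    if not mask.any():
        warnings.warn("all entries missing; reconstruction loss is 0", stacklevel=2)
        return 0.0
    p = np.clip(xhat[mask], _EPS, 1.0 - _EPS)
    xv = x[mask].astype(np.float64)
    return float(-np.sum(xv * np.log(p) + (1.0 - xv) * np.log1p(-p)))


def kl_term(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)).

    Equals ``0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2)``.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if mu.shape != sigma.shape:
        raise ValueError("mu and sigma must have the same shape")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma)))


def _leaky(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, a, _LEAKY_SLOPE * a)


def _leaky_grad(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, np.float32(1.0), np.float32(_LEAKY_SLOPE))


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    # uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) for both weight and bias,
    # the standard default for fully connected layers
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)
    b = rng.uniform(-bound, bound, size=fan_out).astype(np.float32)
    return w, b


class BinaryMutationVAE(BaseEstimator, TransformerMixin):
    """VAE embedding of binary mutation profiles (scikit-learn style).

    Parameters
    ----------
    latent_dim
        Dimension D of the latent space (default 3).
    hidden_sizes
        Sizes of the two hidden layers; ``None`` (default) uses
        ``(max(M // 5, 1), max(M // 10, 1))`` for an M-locus input.
        The decoder mirrors the encoder.
    kl_weight
        Weight ``lambda`` of the KL regularizer (default 1e-4).
    learning_rate, batch_size, epochs
        RMSprop learning rate (1e-4), minibatch size (64) and number of
        training epochs (300).
    random_state
        Seeds weight initialization, shuffling and reparameterization
        noise; fixing it makes ``fit``/``transform`` reproducible.

    Attributes
    ----------
    loss_history_ : list of float
        Mean total loss per epoch (mean over cells of the per-cell
        masked cross-entropy plus weighted KL).
    kl_loss_history_ : list of float
        The weighted-KL component of ``loss_history_`` per epoch;
        identically 0 when ``kl_weight`` is 0.
    n_features_in_ : int
        Number of loci M seen during :meth:`fit`.
    """

    def __init__(
        self,
        latent_dim: int = 3,
        hidden_sizes: Sequence[int] | None = None,
        kl_weight: float = 1e-4,
        learning_rate: float = 1e-4,
        batch_size: int = 64,
        epochs: int = 300,
        random_state: int | None = None,
    ):
        self.latent_dim = latent_dim
        self.hidden_sizes = hidden_sizes
        self.kl_weight = kl_weight
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    # -- data handling -------------------------------------------------
    @staticmethod
    def _as_array(X) -> tuple[np.ndarray, np.ndarray]:
        """Return (float32 matrix with MISSING->0, float32 observed mask)."""
        if isinstance(X, MutationMatrix):
            values = X.values
        else:
            values = np.asarray(X)
        if values.ndim != 2:
            raise ValueError("input must be a 2-D cells x loci matrix")
        mask = (values != MISSING).astype(np.float32)
        dense = np.where(values == MISSING, 0, values).astype(np.float32)
        return dense, mask

    def _validate_params_(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    # -- forward pieces ------------------------------------------------
    def _encode(self, x: np.ndarray):
        p = self.params_
        a1 = x @ p["W1"] + p["b1"]
        h1 = _leaky(a1)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = _leaky(a2)
        mu = h2 @ p["Wm"] + p["bm"]
        lv = h2 @ p["Wv"] + p["bv"]  # log-variance head keeps sigma positive
        return a1, h1, a2, h2, mu, lv

    def _decode(self, z: np.ndarray):
        p = self.params_
        d1 = z @ p["U1"] + p["c1"]
        g1 = _leaky(d1)
        d2 = g1 @ p["U2"] + p["c2"]
        g2 = _leaky(d2)
        d3 = g2 @ p["U3"] + p["c3"]
        with np.errstate(over="ignore"):
            xhat = 1.0 / (1.0 + np.exp(-d3))
        return d1, g1, d2, g2, d3, xhat

    # -- training ------------------------------------------------------
    def fit(self, X, y=None) -> "BinaryMutationVAE":
        """Train the autoencoder on an N x M ternary matrix."""
        self._validate_params_()
        dense, mask = self._as_array(X)
        n, m = dense.shape
        if self.hidden_sizes is None:
            h1, h2 = max(m // 5, 1), max(m // 10, 1)
        else:
            h1, h2 = (int(s) for s in self.hidden_sizes)
        d = self.latent_dim
        rng = np.random.default_rng(self.random_state)

        p: dict[str, np.ndarray] = {}
        p["W1"], p["b1"] = _init_linear(rng, m, h1)
        p["W2"], p["b2"] = _init_linear(rng, h1, h2)
        p["Wm"], p["bm"] = _init_linear(rng, h2, d)
        p["Wv"], p["bv"] = _init_linear(rng, h2, d)
        p["U1"], p["c1"] = _init_linear(rng, d, h2)
        p["U2"], p["c2"] = _init_linear(rng, h2, h1)
        p["U3"], p["c3"] = _init_linear(rng, h1, m)
        self.params_ = p
        vel = {k: np.zeros_like(v) for k, v in p.items()}

        lam = np.float32(self.kl_weight)
        lr = self.learning_rate
        history: list[float] = []
        kl_history: list[float] = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            epoch_kl = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, mb = dense[idx], mask[idx]
                b = len(idx)

                a1, h1a, a2, h2a, mu, lv = self._encode(xb)
                sigma = np.exp(0.5 * lv)
                eps = rng.standard_normal(mu.shape, dtype=np.float32)
                z = mu + sigma * eps
                d1, g1, d2, g2, d3, xhat = self._decode(z)

                ph = np.clip(xhat, _EPS, 1.0 - _EPS)
                recon = -np.sum(mb * (xb * np.log(ph) + (1 - xb) * np.log1p(-ph)))
                kl = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv)
                batch_loss = (recon + lam * kl) / b
                if not np.isfinite(batch_loss):
                    raise TrainingDivergenceError(
                        f"non-finite loss at epoch {epoch + 1}"
                    )
                epoch_loss += float(recon + lam * kl)
                epoch_kl += float(lam * kl)

                # ---- backward (gradients of the batch-mean objective) ----
                inv_b = np.float32(1.0 / b)
                g_d3 = (xhat - xb) * mb * inv_b
                gU3 = g2.T @ g_d3
                gc3 = g_d3.sum(0)
                g_g2 = g_d3 @ p["U3"].T
                g_d2 = g_g2 * _leaky_grad(d2)
                gU2 = g1.T @ g_d2
                gc2 = g_d2.sum(0)
                g_g1 = g_d2 @ p["U2"].T
                g_d1 = g_g1 * _leaky_grad(d1)
                gU1 = z.T @ g_d1
                gc1 = g_d1.sum(0)
                g_z = g_d1 @ p["U1"].T

                g_mu = g_z + (lam * inv_b) * mu
                g_lv = g_z * (0.5 * sigma * eps) + (lam * inv_b) * 0.5 * (
                    np.exp(lv) - 1.0
                )
                gWm = h2a.T @ g_mu
                gbm = g_mu.sum(0)
                gWv = h2a.T @ g_lv
                gbv = g_lv.sum(0)
                g_h2 = g_mu @ p["Wm"].T + g_lv @ p["Wv"].T
                g_a2 = g_h2 * _leaky_grad(a2)
                gW2 = h1a.T @ g_a2
                gb2 = g_a2.sum(0)
                g_h1 = g_a2 @ p["W2"].T
                g_a1 = g_h1 * _leaky_grad(a1)
                gW1 = xb.T @ g_a1
                gb1 = g_a1.sum(0)

                grads = {
                    "W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
                    "Wm": gWm, "bm": gbm, "Wv": gWv, "bv": gbv,
                    "U1": gU1, "c1": gc1, "U2": gU2, "c2": gc2,
                    "U3": gU3, "c3": gc3,
                }
                for k, g in grads.items():
                    v = vel[k]
                    v *= _RMS_DECAY
                    v += (1.0 - _RMS_DECAY) * g * g
                    p[k] -= lr * g / (np.sqrt(v) + _RMS_EPS)
            history.append(epoch_loss / n)
            kl_history.append(epoch_kl / n)

        self.loss_history_ = history
        self.kl_loss_history_ = kl_history
        self.n_features_in_ = m
        return self

    def transform(self, X) -> np.ndarray:
        """Posterior-mean latent coordinates (N, D); deterministic."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        dense, _ = self._as_array(X)
        if dense.shape[1] != self.n_features_in_:
            raise ValueError(
                f"matrix has {dense.shape[1]} loci, model was trained on "
                f"{self.n_features_in_}"
            )
        *_, mu, _lv = self._encode(dense)
        return mu.astype(np.float64)

    def reconstruct(self, X) -> np.ndarray:
        """Decoder probabilities for the posterior-mean latent codes."""
        z = self.transform(X).astype(np.float32)
        *_, xhat = self._decode(z)
        return xhat.astype(np.float64)


# -- functional wrappers ----------------------------------------------

def train_vae(data: MutationMatrix, **config) -> BinaryMutationVAE:
    """Train a :class:`BinaryMutationVAE` on a mutation matrix.

    Keyword arguments are forwarded to the estimator constructor
    (``latent_dim``, ``epochs``, ``random_state``, ...).
    """
    return BinaryMutationVAE(**config).fit(data)


def embed(data: MutationMatrix, model: BinaryMutationVAE) -> LatentEmbedding:
    """Embed each cell at its posterior mean using a trained model."""
    coords = model.transform(data)
    ids = data.cell_ids if isinstance(data, MutationMatrix) else []
    return LatentEmbedding(coords, cell_ids=list(ids))
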