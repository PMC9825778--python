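"""Gaussian-mixture clustering of latent embeddings with BIC model selection.

The number of subpopulations is unknown a priori.  Starting from a single
component, the scan fits mixtures with k = 1, 2, 3, ... components and
tracks the Bayesian information criterion; it stops once the incumbent
minimum has not improved for ``patience`` consecutive values of k (default
10) or a predefined maximum is reached, and returns the assignment of the
best-scoring k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from bmvae.vae import LatentEmbedding

_DEFAULT_PATIENCE = 10
_REG_COVAR = 1e-6
_N_INIT = 5


class DegenerateFitError(RuntimeError):
    """Raised when every attempted mixture fit fails."""


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels with the BIC scan that produced them."""

    labels: np.ndarray  # (N,) ints in 0..K-1
    n_clusters: int
    bic_trace: list[tuple[int, float]] = field(default_factory=list)
    patience: int = _DEFAULT_PATIENCE
    max_clusters: int | None = None
    selected_k: int | None = None  # scan k minimizing BIC (before compaction)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if uniq.min() < 0 or uniq.max() >= self.n_clusters:
            raise ValueError("labels must lie in 0..n_clusters-1")
        if len(uniq) != self.n_clusters:
            raise ValueError("every cluster must have at least one member")


def _coords(embedding) -> np.ndarray:
    if isinstance(embedding, LatentEmbedding):
        return embedding.coords
    return np.asarray(embedding, dtype=np.float64)


def fit_gmm(
    embedding, k: int, seed: int | None = None, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Fit a k-component full-covariance Gaussian mixture by EM.

    Returns maximum-posterior labels and the BIC
    (``-2 log L + p ln N``) of the fitted model.
    """
    x = _coords(embedding)
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k={k} outside 1..{x.shape[0]}")
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=_REG_COVAR,
        n_init=_N_INIT,
        init_params="kmeans",
        max_iter=max_iter,
        random_state=seed,
    )
    try:
        with warnings.catch_warnings():
            # identical cells give duplicate latent points; k-means init then
            # finds fewer distinct centers than asked, which is fine here
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = gmm.fit_predict(x)
    except ValueError as exc:  # singular covariance and friends
        raise DegenerateFitError(f"EM failed for k={k}: {exc}") from exc
    return labels, float(gmm.bic(x))


class GaussianMixtureBIC(BaseEstimator, ClusterMixin):
    """BIC-scanned Gaussian mixture clusterer (scikit-learn style).

    Parameters
    ----------
    max_clusters
        Largest k to consider; ``None`` (default) uses ``min(N - 1, 100)``.
    patience
        Stop after this many consecutive k values without a new BIC
        minimum (default 10); ties keep the smaller k.
    min_clusters
        Smallest k to consider (default 1).  Raising it restricts the
        scan window when small k are known to be grossly
        underparameterized; intended as a large-problem runtime control.
    em_max_iter
        EM iteration cap per mixture fit (default 100), another
        large-problem runtime control.
    random_state
        Seeds the EM restarts at every k.

    Attributes
    ----------
    labels_ : (N,) int array, compacted to 0..n_clusters_-1
    n_clusters_ : number of non-empty clusters of the best model
    bic_trace_ : list of (k, BIC) in scan order
    selected_k_ : the scanned k with minimum BIC
    """

    def __init__(
        self,
        max_clusters: int | None = None,
        patience: int = _DEFAULT_PATIENCE,
        min_clusters: int = 1,
        em_max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.max_clusters = max_clusters
        self.patience = patience
        self.min_clusters = min_clusters
        self.em_max_iter = em_max_iter
        self.random_state = random_state

    def fit(self, X, y=None) -> "GaussianMixtureBIC":
        x = _coords(X)
        n = x.shape[0]
        max_k = self.max_clusters if self.max_clusters is not None else min(n - 1, 100)
        max_k = max(1, min(max_k, n))
        min_k = self.min_clusters
        if not 1 <= min_k <= max_k:
            raise ValueError(f"min_clusters={min_k} outside 1..max_clusters ({max_k})")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

        trace: list[tuple[int, float]] = []
        results: dict[int, np.ndarray] = {}
        best_k, best_bic = None, np.inf
        n_failures = 0
        for k in range(min_k, max_k + 1):
            try:
                labels, bic = fit_gmm(
                    x, k, seed=self.random_state, max_iter=self.em_max_iter
                )
            except DegenerateFitError:
                n_failures += 1
                continue
            trace.append((k, bic))
            results[k] = labels
            if bic < best_bic:  # strict improvement resets the counter
                best_bic, best_k = bic, k
            elif k - best_k >= self.patience:
                break
        if best_k is None:
            raise DegenerateFitError(f"all {n_failures} mixture fits degenerate")

        raw = results[best_k]
        # drop empty components, compact labels to 0..K-1
        uniq, compact = np.unique(raw, return_inverse=True)
        self.labels_ = compact.astype(np.int64)
        self.n_clusters_ = len(uniq)
        self.bic_trace_ = trace
        self.selected_k_ = best_k
        self._max_k_used_ = max_k
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def select_clusters(
    embedding,
    max_clusters: int | None = None,
    patience: int = _DEFAULT_PATIENCE,
    min_clusters: int = 1,
    em_max_iter: int = 100,
    seed: int | None = None,
) -> ClusterAssignment:
    """Scan k by BIC and return the best assignment (see class docs)."""
    est = GaussianMixtureBIC(
        max_clusters=max_clusters,
        patience=patience,
        min_clusters=min_clusters,
        em_max_iter=em_max_iter,
        random_state=seed,
    ).fit(embedding)
    return ClusterAssignment(
        labels=est.labels_,
        n_clusters=est.n_clusters_,
        bic_trace=est.bic_trace_,
        patience=patience,
        max_clusters=est._max_k_used_,
        selected_k=est.selected_k_,
    )
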