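"""Gibbs-sampling estimation of clonal genotypes and global error rates.

Given cluster labels and the observed ternary matrix, each cluster k is
assumed to share one binary genotype row ``E[k]``.  An observation is
corrupted independently per entry: a true absent site is read as 1 with
false-positive rate ``alpha``, a true present site is read as 0 with
false-negative rate ``beta`` (allelic dropout).  Under a uniform prior on
each genotype entry, the posterior odds of ``E[k, j] = 1`` factorize over
the cluster's cells, so both the per-entry posterior and the
maximum-likelihood error-rate updates have closed forms in the counts of
observed 0s and 1s per (cluster, locus) pair; missing entries contribute
to neither.  The sampler alternates drawing ``E`` from its posterior with
rate updates, starting from ``alpha = beta = 0.01``, until both rates
stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bmvae.io import MISSING, MutationMatrix

_RATE_CLIP = 1e-6
_DEFAULT_TOL = 1e-4
_DEFAULT_MAX_ITER = 200
_STABLE_ITERS = 5  # consecutive sub-tol iterations required to declare convergence
_ALPHA_INIT = 0.01
_BETA_INIT = 0.01


@dataclass
class ClonalGenotypes:
    """Inferred K x M binary genotypes with global error-rate estimates."""

    genotypes: np.ndarray  # (K, M) ints in {0, 1}
    alpha: float
    beta: float
    posterior: np.ndarray  # (K, M) marginal p(E_kj = 1) at the final rates
    n_iterations: int
    converged: bool = True

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.posterior = np.asarray(self.posterior, dtype=np.float64)
        if self.genotypes.shape != self.posterior.shape:
            raise ValueError("genotypes and posterior must have the same shape")
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("error rates must lie in [0, 1]")


def _values(data) -> np.ndarray:
    return data.values if isinstance(data, MutationMatrix) else np.asarray(data)


def _count_matrix(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per (cluster, locus) counts of observed 1s and 0s."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("one label per cell required")
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    k = int(labels.max()) + 1
    sizes = np.bincount(labels, minlength=k)
    if (sizes == 0).any():
        empty = int(np.flatnonzero(sizes == 0)[0])
        raise ValueError(f"cluster {empty} has no cells")
    m = values.shape[1]
    ones = np.zeros((k, m), dtype=np.float64)
    zeros = np.zeros((k, m), dtype=np.float64)
    np.add.at(ones, labels, (values == 1).astype(np.float64))
    np.add.at(zeros, labels, (values == 0).astype(np.float64))
    return ones, zeros


def genotype_posterior(data, labels, alpha: float, beta: float) -> np.ndarray:
    """Marginal posterior p(E_kj = 1 | X, alpha, beta, labels), shape (K, M).

    Uses a uniform prior on each genotype entry and the error model
    p(X=1|E=0) = alpha, p(X=0|E=1) = beta; products over a cluster's
    cells are taken in log space, skipping missing entries.  A
    cluster-locus pair with no observed entries gets posterior 0.5.
    """
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must lie strictly in (0, 1)")
    values = _values(data)
    n1, n0 = _count_matrix(values, labels)
    # log-likelihood of the column under each genotype state
    log_e1 = n1 * np.log1p(-beta) + n0 * np.log(beta)
    log_e0 = n1 * np.log(alpha) + n0 * np.log1p(-alpha)
    # p(E=1) = 1 / (1 + exp(log_e0 - log_e1)), computed stably
    delta = np.clip(log_e0 - log_e1, -700, 700)
    return 1.0 / (1.0 + np.exp(delta))


def update_error_rates(
    data,
    genotypes: np.ndarray,
    labels,
    alpha_fallback: float = np.nan,
    beta_fallback: float = np.nan,
) -> tuple[float, float]:
    """Maximum-likelihood error rates given binary clone genotypes.

    alpha = (# observed 1s where the expanded genotype is 0) /
            (# observed entries where the expanded genotype is 0),
    and symmetrically beta over genotype-1 positions with observed 0s.
    Missing entries count in neither numerator nor denominator.  An
    empty denominator returns the corresponding fallback value.
    """
    values = _values(data)
    labels = np.asarray(labels, dtype=np.int64)
    genotypes = np.asarray(genotypes)
    e_cells = genotypes[labels]  # (N, M) expansion
    observed = values != MISSING
    at0 = observed & (e_cells == 0)
    at1 = observed & (e_cells == 1)
    n_at0 = at0.sum()
    n_at1 = at1.sum()
    alpha = float((values[at0] == 1).sum() / n_at0) if n_at0 else float(alpha_fallback)
    beta = float((values[at1] == 0).sum() / n_at1) if n_at1 else float(beta_fallback)
    return alpha, beta


class GibbsGenotyper:
    """Alternating genotype sampler and error-rate maximizer.

    Parameters
    ----------
    max_iter, tol
        Stop once |change in alpha| and |change in beta| stay below
        ``tol`` (default 1e-4) for 5 consecutive iterations, or after
        ``max_iter`` (default 200) iterations.
    alpha_init, beta_init
        Starting error rates (default 0.01 each).
    random_state
        Seeds the Bernoulli draws of the genotype matrix.

    Attributes (after :meth:`fit`)
    ------------------------------
    genotypes_ : (K, M) binary genotype per cluster, thresholded from the
        final posterior at 0.5 (an exact tie calls no mutation)
    alpha_, beta_ : converged error-rate estimates
    posterior_ : (K, M) marginals at the converged rates
    n_iter_ : iterations performed
    converged_ : whether the stability criterion was met
    """

    def __init__(
        self,
        max_iter: int = _DEFAULT_MAX_ITER,
        tol: float = _DEFAULT_TOL,
        alpha_init: float = _ALPHA_INIT,
        beta_init: float = _BETA_INIT,
        random_state: int | None = None,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.alpha_init = alpha_init
        self.beta_init = beta_init
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_iter": self.max_iter,
            "tol": self.tol,
            "alpha_init": self.alpha_init,
            "beta_init": self.beta_init,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "GibbsGenotyper":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, labels) -> "GibbsGenotyper":
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        values = _values(X)
        labels = np.asarray(labels, dtype=np.int64)
        n1, n0 = _count_matrix(values, labels)  # validates labels
        rng = np.random.default_rng(self.random_state)

        def posterior(alpha: float, beta: float) -> np.ndarray:
            log_e1 = n1 * np.log1p(-beta) + n0 * np.log(beta)
            log_e0 = n1 * np.log(alpha) + n0 * np.log1p(-alpha)
            delta = np.clip(log_e0 - log_e1, -700, 700)
            return 1.0 / (1.0 + np.exp(delta))

        alpha = float(np.clip(self.alpha_init, _RATE_CLIP, 1 - _RATE_CLIP))
        beta = float(np.clip(self.beta_init, _RATE_CLIP, 1 - _RATE_CLIP))
        stable = 0
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            post = posterior(alpha, beta)
            e_sample = (rng.random(post.shape) < post).astype(np.int8)
            new_alpha, new_beta = update_error_rates(
                values, e_sample, labels, alpha_fallback=alpha, beta_fallback=beta
            )
            new_alpha = float(np.clip(new_alpha, _RATE_CLIP, 1 - _RATE_CLIP))
            new_beta = float(np.clip(new_beta, _RATE_CLIP, 1 - _RATE_CLIP))
            if abs(new_alpha - alpha) < self.tol and abs(new_beta - beta) < self.tol:
                stable += 1
            else:
                stable = 0
            alpha, beta = new_alpha, new_beta
            if stable >= _STABLE_ITERS:
                converged = True
                break

        final_post = posterior(alpha, beta)
        self.genotypes_ = (final_post > 0.5).astype(np.int8)
        self.posterior_ = final_post
        self.alpha_ = alpha
        self.beta_ = beta
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def result_(self) -> ClonalGenotypes:
        return ClonalGenotypes(
            genotypes=self.genotypes_,
            alpha=self.alpha_,
            beta=self.beta_,
            posterior=self.posterior_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
        )


def gibbs_infer(
    data,
    labels,
    max_iter: int = _DEFAULT_MAX_ITER,
    seed: int | None = None,
    tol: float = _DEFAULT_TOL,
    alpha_init: float = _ALPHA_INIT,
    beta_init: float = _BETA_INIT,
) -> ClonalGenotypes:
    """Run the Gibbs sampler and return the inferred clonal genotypes."""
    est = GibbsGenotyper(
        max_iter=max_iter,
        tol=tol,
        alpha_init=alpha_init,
        beta_init=beta_init,
        random_state=seed,
    ).fit(data, labels)
    return est.result_()
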