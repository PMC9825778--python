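"""End-to-end pipeline: embed, cluster, genotype, write outputs."""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from bmvae import io as bio
from bmvae.cluster import ClusterAssignment, select_clusters
from bmvae.genotype import ClonalGenotypes, gibbs_infer
from bmvae.io import MutationMatrix
from bmvae.vae import BinaryMutationVAE, LatentEmbedding, embed

logger = logging.getLogger("bmvae")


@dataclass
class PipelineConfig:
    """All stage settings plus a single top-level seed.

    The top-level seed deterministically derives independent seeds for
    the VAE, the mixture scan and the Gibbs sampler, so one integer
    reproduces the whole run.
    """

    seed: int = 0
    # VAE
    latent_dim: int = 3
    hidden_sizes: tuple[int, int] | None = None
    kl_weight: float = 1e-4
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 300
    # clustering
    max_clusters: int | None = None
    patience: int = 10
    min_clusters: int = 1
    gmm_max_iter: int = 100
    # genotyping
    gibbs_max_iter: int = 200
    gibbs_tol: float = 1e-4
    alpha_init: float = 0.01
    beta_init: float = 0.01
    # io
    missing_code: int = 3
    orientation: str = "cells-as-rows"

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        vae_s, gmm_s, gibbs_s = (
            int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(3)
        )
        return {"vae": vae_s, "gmm": gmm_s, "gibbs": gibbs_s}


def run_pipeline(
    data: "MutationMatrix | str | Path",
    config: PipelineConfig | None = None,
    out_dir: "str | Path | None" = None,
) -> tuple[ClusterAssignment, ClonalGenotypes, LatentEmbedding]:
    """Run embedding, clustering and genotype estimation on one matrix.

    ``data`` may be a :class:`MutationMatrix` or a path to a delimited
    text file.  If ``out_dir`` is given, all result files are written
    there via :func:`bmvae.io.write_results`.
    """
    config = config or PipelineConfig()
    if not isinstance(data, MutationMatrix):
        data = bio.read_mutation_matrix(
            data, missing_code=config.missing_code, orientation=config.orientation
        )
    seeds = config.stage_seeds()

    t0 = time.time()
    model = BinaryMutationVAE(
        latent_dim=config.latent_dim,
        hidden_sizes=config.hidden_sizes,
        kl_weight=config.kl_weight,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        random_state=seeds["vae"],
    ).fit(data)
    embedding = embed(data, model)
    t1 = time.time()
    logger.info("VAE: %d epochs in %.1fs (final loss %.3f)",
                config.epochs, t1 - t0, model.loss_history_[-1])

    assignment = select_clusters(
        embedding,
        max_clusters=config.max_clusters,
        patience=config.patience,
        min_clusters=config.min_clusters,
        em_max_iter=config.gmm_max_iter,
        seed=seeds["gmm"],
    )
    t2 = time.time()
    logger.info("GMM: selected K=%d (scanned %d..%d) in %.1fs",
                assignment.n_clusters, assignment.bic_trace[0][0],
                assignment.bic_trace[-1][0], t2 - t1)

    genotypes = gibbs_infer(
        data,
        assignment.labels,
        max_iter=config.gibbs_max_iter,
        tol=config.gibbs_tol,
        alpha_init=config.alpha_init,
        beta_init=config.beta_init,
        seed=seeds["gibbs"],
    )
    t3 = time.time()
    logger.info("Gibbs: alpha=%.4f beta=%.4f after %d iterations in %.1fs",
                genotypes.alpha, genotypes.beta, genotypes.n_iterations, t3 - t2)

    if out_dir is not None:
        bio.write_results(
            assignment, genotypes, embedding, out_dir,
            seed=config.seed, config=asdict(config),
        )
    return assignment, genotypes, embedding
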