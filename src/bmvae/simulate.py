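"""Synthetic single-cell mutation datasets with known clonal structure.

The generator mimics the observation process of single-cell SNV calling:
K clones with distinct, tree-consistent binary genotypes over M loci;
N cells assigned to clones with random proportions; a fraction of cells
replaced by doublets (the entrywise OR of two clones' genotypes); then
entrywise corruption — a true 1 observed as 0 with false-negative rate
``beta`` (allelic dropout), a true 0 observed as 1 with false-positive
rate ``alpha`` — and random masking of entries as missing.

Named presets reproduce the benchmark grids used for evaluation: a
false-negative sweep (D1), cell-count and locus-count sweeps (D2, D3),
a clone-count sweep at 2000 cells x 2000 loci (D4), and two small-data
series (D5, D6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from bmvae.io import MISSING, MutationMatrix

_PRESET_GRIDS: dict[str, dict] = {
    "D1": {"factor": "beta", "levels": [0.3, 0.4, 0.5, 0.6]},
    "D2": {"factor": "n_cells", "levels": [500, 1000, 2000, 5000]},
    "D3": {"factor": "n_loci", "levels": [500, 1000, 2000, 5000]},
    "D4": {
        "factor": "n_clones",
        "levels": [20, 30, 40, 50],
        "fixed": {"n_cells": 2000, "n_loci": 2000},
    },
    "D5": {
        "factor": "n_cells",
        "levels": [100, 200, 300, 400, 500],
        "fixed": {"n_loci": 100, "n_clones": 5},
    },
    "D6": {
        "factor": "n_loci",
        "levels": [20, 30, 40, 50, 60],
        "fixed": {"n_cells": 500, "n_clones": 5},
    },
}


@dataclass
class SimulationConfig:
    """Generator settings; defaults give the standard benchmark regime."""

    alpha: float = 0.01
    beta: float = 0.3
    n_cells: int = 1000
    n_loci: int = 1000
    n_clones: int = 20
    missing_rate: float = 0.02
    doublet_rate: float = 0.10
    min_clone_fraction: float = 0.01
    seed: int | None = None

    def validate(self) -> None:
        if self.n_clones > self.n_cells:
            raise ValueError("need at least one cell per clone (K <= N)")
        if self.n_clones > self.n_loci:
            raise ValueError("need at least one locus per clone (K <= M)")
        for name in ("alpha", "beta", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name}={v} outside [0, 1)")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate outside [0, 1)")
        if self.min_clone_fraction * self.n_clones >= 1:
            raise ValueError("min_clone_fraction too large for this many clones")


@dataclass
class SimulatedDataset:
    """Observed matrix plus the ground truth it was generated from."""

    observed: MutationMatrix
    true_labels: np.ndarray  # (N,) clone index per cell (host clone for doublets)
    true_clone_genotypes: np.ndarray  # (K, M) binary
    true_cell_genotypes: np.ndarray  # (N, M) binary, pre-corruption
    doublet_flags: np.ndarray  # (N,) bool
    config: SimulationConfig = field(default_factory=SimulationConfig)


def _random_clonal_tree(rng: np.random.Generator, k: int) -> np.ndarray:
    """Random rooted tree over k clones: parent[i] < i, parent[0] = -1."""
    parent = np.full(k, -1, dtype=np.int64)
    for i in range(1, k):
        parent[i] = rng.integers(0, i)
    return parent


def _clone_genotypes(rng: np.random.Generator, k: int, m: int) -> np.ndarray:
    """Tree-consistent clone genotypes: mutations placed uniformly on the
    tree nodes (each node keeps >= 1 private mutation), each clone carrying
    the union of mutations on its root path."""
    parent = _random_clonal_tree(rng, k)
    while True:
        node_of_mutation = rng.integers(0, k, size=m)
        if len(np.unique(node_of_mutation)) == k:
            break
    genotypes = np.zeros((k, m), dtype=np.int8)
    order = range(k)  # parent[i] < i, so a single pass suffices
    for node in order:
        if parent[node] >= 0:
            genotypes[node] = genotypes[parent[node]]
        genotypes[node, node_of_mutation == node] = 1
    return genotypes


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset; bit-identical for a fixed ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m, k = config.n_cells, config.n_loci, config.n_clones

    clone_genotypes = _clone_genotypes(rng, k, m)

    # clone proportions: uniform on the sub-simplex {p: p_i >= floor}.
    # The affine image floor + (1 - k*floor) * Dirichlet(1) of the uniform
    # distribution on the full simplex is exactly that distribution
    # (the sub-simplex is a scaled translate of the simplex), so no
    # rejection on the floor is needed — rejection is astronomically
    # unlikely to accept for large k (probability (1 - k*floor)^(k-1)).
    floor = config.min_clone_fraction
    while True:
        props = floor + (1.0 - k * floor) * rng.dirichlet(np.ones(k))
        labels = rng.choice(k, size=n, p=props)
        if len(np.unique(labels)) == k:
            break

    cell_genotypes = clone_genotypes[labels].copy()

    n_doublets = int(np.floor(config.doublet_rate * n))
    doublet_flags = np.zeros(n, dtype=bool)
    if n_doublets:
        chosen = rng.choice(n, size=n_doublets, replace=False)
        doublet_flags[chosen] = True
        for i in chosen:
            host = labels[i]
            other = int(rng.integers(0, k - 1))
            if other >= host:
                other += 1  # uniform over the k-1 non-host clones
            cell_genotypes[i] = np.maximum(
                clone_genotypes[host], clone_genotypes[other]
            )

    observed = cell_genotypes.copy()
    u = rng.random((n, m))
    observed[(cell_genotypes == 1) & (u < config.beta)] = 0
    observed[(cell_genotypes == 0) & (u < config.alpha)] = 1
    if config.missing_rate > 0:
        observed[rng.random((n, m)) < config.missing_rate] = MISSING

    return SimulatedDataset(
        observed=MutationMatrix(observed),
        true_labels=labels.astype(np.int64),
        true_clone_genotypes=clone_genotypes,
        true_cell_genotypes=cell_genotypes,
        doublet_flags=doublet_flags,
        config=config,
    )


def preset(name: str, level_index: int, replicate_seed: int | None = None) -> SimulationConfig:
    """Benchmark preset config: dataset name (D1..D6) and grid level.

    Examples: ``preset("D1", 3)`` is the hardest false-negative level
    (beta=0.6); ``preset("D4", 0)`` is 20 clones at 2000 cells x 2000
    loci; ``preset("D6", 1)`` is 30 loci at 500 cells, 5 clones.
    """
    if name not in _PRESET_GRIDS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESET_GRIDS)}")
    grid = _PRESET_GRIDS[name]
    levels = grid["levels"]
    if not 0 <= level_index < len(levels):
        raise ValueError(
            f"level_index {level_index} out of range for {name} (0..{len(levels) - 1})"
        )
    cfg = SimulationConfig(seed=replicate_seed)
    for key, val in grid.get("fixed", {}).items():
        setattr(cfg, key, val)
    setattr(cfg, grid["factor"], levels[level_index])
    cfg.validate()
    return cfg


def realized_error_rates(dataset: SimulatedDataset) -> tuple[float, float]:
    """Empirical corruption rates of a simulated dataset (excluding
    missing entries); useful for checking generator calibration."""
    truth = dataset.true_cell_genotypes
    obs = dataset.observed.values
    seen = obs != MISSING
    ones = seen & (truth == 1)
    zeros = seen & (truth == 0)
    beta_hat = float((obs[ones] == 0).mean()) if ones.any() else np.nan
    alpha_hat = float((obs[zeros] == 1).mean()) if zeros.any() else np.nan
    return alpha_hat, beta_hat
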