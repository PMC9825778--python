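"""Evaluation of clustering and genotyping against simulated ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score


@dataclass
class EvaluationReport:
    """Scores of one inference run against ground truth."""

    ari: float
    genotyping_accuracy: float
    k_true: int
    k_inferred: int

    def as_dict(self) -> dict:
        return {
            "ari": self.ari,
            "genotyping_accuracy": self.genotyping_accuracy,
            "k_true": self.k_true,
            "k_inferred": self.k_inferred,
        }


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement of two partitions of the same cells.

    Symmetric and invariant to label permutation; 1 for identical
    partitions, ~0 for independent ones.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    if labels_a.size < 2:
        raise ValueError("need at least two cells")
    return float(adjusted_rand_score(labels_a, labels_b))


def genotyping_accuracy(true_cell_genotypes, inferred_genotypes, inferred_labels) -> float:
    """Fraction of cell-by-locus mutational states recovered correctly.

    Inferred clone genotypes are expanded to cells via the inferred
    labels and compared to the true cell genotype matrix over all N*M
    positions (the simulated truth is defined even where the observation
    was missing).
    """
    truth = np.asarray(true_cell_genotypes)
    genotypes = np.asarray(inferred_genotypes)
    labels = np.asarray(inferred_labels, dtype=np.int64)
    if labels.shape[0] != truth.shape[0]:
        raise ValueError("one label per cell required")
    if labels.min() < 0 or labels.max() >= genotypes.shape[0]:
        raise ValueError("label out of range for the genotype matrix")
    if genotypes.shape[1] != truth.shape[1]:
        raise ValueError("locus count mismatch")
    expanded = genotypes[labels]
    return float((expanded == truth).mean())


def evaluate_run(
    true_labels,
    inferred_labels,
    true_cell_genotypes,
    inferred_genotypes,
    exclude_doublets: bool = False,
    doublet_flags=None,
) -> EvaluationReport:
    """Score one run; optionally restrict to non-doublet cells."""
    true_labels = np.asarray(true_labels)
    inferred_labels = np.asarray(inferred_labels)
    truth = np.asarray(true_cell_genotypes)
    if exclude_doublets:
        if doublet_flags is None:
            raise ValueError("doublet_flags required to exclude doublets")
        keep = ~np.asarray(doublet_flags, dtype=bool)
        true_labels = true_labels[keep]
        inferred_labels = inferred_labels[keep]
        truth = truth[keep]
    return EvaluationReport(
        ari=adjusted_rand_index(true_labels, inferred_labels),
        genotyping_accuracy=genotyping_accuracy(truth, inferred_genotypes, inferred_labels),
        k_true=len(np.unique(true_labels)),
        k_inferred=len(np.unique(inferred_labels)),
    )
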