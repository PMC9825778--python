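"""Reading and writing mutation matrices and pipeline outputs.

Observed single-cell genotype matrices are delimited text (TSV/CSV) with
entries in ``{0, 1, missing_code}``; the on-disk missing marker defaults
to ``3`` following the genotype-matrix convention of tools such as SCITE
and SiFit.  Internally missing entries are stored as :data:`MISSING`
(``-1``) in an ``int8`` array so that ``{0, 1}`` keep their arithmetic
meaning.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from bmvae.cluster import ClusterAssignment
    from bmvae.genotype import ClonalGenotypes
    from bmvae.vae import LatentEmbedding

#: Internal sentinel for an unobserved entry.
MISSING: int = -1

#: Default on-disk missing marker (SCITE / SiFit convention).
DEFAULT_MISSING_CODE: int = 3


class MatrixFormatError(ValueError):
    """Raised when an input file cannot be parsed as a genotype matrix."""


@dataclass
class MutationMatrix:
    """An N-cell x M-locus ternary observation matrix.

    Attributes
    ----------
    values
        ``int8`` array of shape (N, M) with entries in ``{0, 1, MISSING}``;
        cells are rows.
    cell_ids, locus_ids
        Unique string identifiers for rows and columns.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one cell and one locus")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.locus_ids:
            self.locus_ids = [f"locus_{j}" for j in range(m)]
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} cells")
        if len(self.locus_ids) != m:
            raise ValueError(f"{len(self.locus_ids)} locus_ids for {m} loci")
        if len(set(self.cell_ids)) != n or len(set(self.locus_ids)) != m:
            raise ValueError("cell_ids and locus_ids must be unique")
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"entry at cell {i}, locus {j} is {self.values[i, j]}; "
                f"expected 0, 1 or MISSING ({MISSING})"
            )
        if not (self.values != MISSING).any():
            raise ValueError("matrix has no observed (non-missing) entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean (N, M) mask, True where the entry was observed."""
        return self.values != MISSING


def _sniff_delimiter(sample: str) -> str:
    if "\t" in sample:
        return "\t"
    if "," in sample:
        return ","
    return None  # whitespace-separated single column / tokens


def read_mutation_matrix(
    path: str | os.PathLike,
    missing_code: int = DEFAULT_MISSING_CODE,
    orientation: str = "cells-as-rows",
    delimiter: str | None = None,
) -> MutationMatrix:
    """Read a delimited-text genotype matrix.

    Parameters
    ----------
    path
        TSV/CSV file; delimiter auto-detected unless given. An optional
        header row / first column of non-numeric tokens is treated as
        locus / cell identifiers.
    missing_code
        Integer marking unobserved entries in the file (default 3).
    orientation
        ``"cells-as-rows"`` (default) or ``"cells-as-columns"``; the
        returned matrix is always cells-as-rows.
    """
    if orientation not in ("cells-as-rows", "cells-as-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    delim = delimiter if delimiter is not None else _sniff_delimiter(lines[0])

    rows = [ln.split(delim) for ln in lines]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MatrixFormatError(f"{path}: ragged rows (widths {sorted(widths)})")

    def _is_int(tok: str) -> bool:
        tok = tok.strip()
        return tok.lstrip("+-").isdigit()

    # a header row contains no integer tokens at all
    header: list[str] | None = None
    if not any(_is_int(t) for t in rows[0]):
        header = [t.strip() for t in rows[0]]
        rows = rows[1:]
        if not rows:
            raise MatrixFormatError(f"{path}: header but no data rows")
    row_ids: list[str] | None = None
    if rows and not _is_int(rows[0][0]):
        row_ids = [r[0].strip() for r in rows]
        rows = [r[1:] for r in rows]
        if header is not None and len(header) == len(rows[0]) + 1:
            header = header[1:]

    values = np.empty((len(rows), len(rows[0])), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            tok = tok.strip()
            if not _is_int(tok):
                raise MatrixFormatError(
                    f"{path}: unparseable token {tok!r} at data row {i}, column {j}"
                )
            v = int(tok)
            if v == missing_code:
                values[i, j] = MISSING
            elif v in (0, 1):
                values[i, j] = v
            else:
                raise ValueError(
                    f"{path}: entry {v} at data row {i}, column {j} is outside "
                    f"{{0, 1, {missing_code}}}"
                )

    col_ids = header
    if orientation == "cells-as-columns":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return MutationMatrix(
        values,
        cell_ids=list(row_ids) if row_ids else [],
        locus_ids=list(col_ids) if col_ids else [],
    )


def write_mutation_matrix(
    matrix: MutationMatrix,
    path: str | os.PathLike,
    missing_code: int = DEFAULT_MISSING_CODE,
    delimiter: str = "\t",
) -> None:
    """Write a genotype matrix as delimited text (no header), cells as rows."""
    out = matrix.values.astype(np.int64).copy()
    out[out == MISSING] = missing_code
    np.savetxt(path, out, fmt="%d", delimiter=delimiter)


def write_results(
    assignment: "ClusterAssignment",
    genotypes: "ClonalGenotypes",
    embedding: "LatentEmbedding",
    out_dir: str | os.PathLike,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write all pipeline outputs to ``out_dir`` as delimited text.

    Produces ``labels.tsv`` (cell_id, label), ``genotypes.tsv`` (K x M),
    ``latent.tsv`` (cell_id + D coordinates) and ``summary.yaml`` (K,
    alpha, beta, seed and a config echo).  Returns the paths keyed by
    artifact name.
    """
    n = len(assignment.labels)
    if embedding.coords.shape[0] != n:
        raise ValueError(
            f"embedding has {embedding.coords.shape[0]} cells but assignment has {n}"
        )
    if genotypes.genotypes.shape[0] != assignment.n_clusters:
        raise ValueError(
            f"genotypes have {genotypes.genotypes.shape[0]} clusters but "
            f"assignment selected {assignment.n_clusters}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["labels"] = out_dir / "labels.tsv"
    with open(paths["labels"], "w") as fh:
        fh.write("cell_id\tlabel\n")
        for cid, lab in zip(embedding.cell_ids, assignment.labels):
            fh.write(f"{cid}\t{int(lab)}\n")

    paths["genotypes"] = out_dir / "genotypes.tsv"
    np.savetxt(paths["genotypes"], genotypes.genotypes.astype(int), fmt="%d", delimiter="\t")

    paths["latent"] = out_dir / "latent.tsv"
    with open(paths["latent"], "w") as fh:
        d = embedding.coords.shape[1]
        fh.write("cell_id\t" + "\t".join(f"z{k}" for k in range(d)) + "\n")
        for cid, row in zip(embedding.cell_ids, embedding.coords):
            fh.write(cid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")

    paths["summary"] = out_dir / "summary.yaml"
    summary = {
        "n_clusters": int(assignment.n_clusters),
        "alpha": float(genotypes.alpha),
        "beta": float(genotypes.beta),
        "bic_trace": [[int(k), float(b)] for k, b in assignment.bic_trace],
        "seed": seed,
        "config": config or {},
    }
    with open(paths["summary"], "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return paths


def read_labels(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    """Read a ``labels.tsv`` written by :func:`write_results`."""
    cell_ids: list[str] = []
    labels: list[int] = []
    with open(path) as fh:
        next(fh)  # header
        for ln in fh:
            cid, lab = ln.rstrip("\n").split("\t")
            cell_ids.append(cid)
            labels.append(int(lab))
    return cell_ids, np.asarray(labels, dtype=np.int64)
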