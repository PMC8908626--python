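"""Core matrix containers and cellranger-style MTX bundle I/O.

A :class:`CountMatrix` is a dense genes x cells integer matrix with gene and
cell identifiers; mitochondrial genes are flagged by the ``MT-`` identifier
prefix. On-disk exchange uses a MatrixMarket coordinate file plus
``features.tsv`` / ``barcodes.tsv`` sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "ScaledMatrix",
    "MITO_PREFIX",
    "read_mtx",
    "write_mtx",
]

MITO_PREFIX = "MT-"


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer UMI counts."""

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def mito_mask(self) -> np.ndarray:
        """Boolean flag per gene; mitochondrial genes carry the MT- prefix."""
        return np.array([str(g).startswith(MITO_PREFIX) for g in self.gene_ids])

    def total_counts(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return self.counts.sum(axis=0)

    def detected_genes(self) -> np.ndarray:
        """Per-cell number of genes with count > 0."""
        return (self.counts > 0).sum(axis=0)

    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of counts mapping to mitochondrial genes."""
        totals = self.total_counts().astype(float)
        mito = self.counts[self.mito_mask].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        return frac

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.counts[:, mask], self.gene_ids, self.cell_ids[mask])


@dataclass
class NormalizedMatrix:
    """Genes x cells log-normalized expression (ln1p of library-scaled counts)."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float = 10_000.0
    provenance: object | None = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ScaledMatrix:
    """Genes x cells gene-wise standardized expression.

    Zero-variance genes are removed before standardization and listed in
    ``dropped_genes``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    dropped_genes: list = field(default_factory=list)
    clip: float = 10.0

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def write_mtx(matrix: CountMatrix, path: str | Path) -> Path:
    """Write a MatrixMarket bundle (matrix.mtx, features.tsv, barcodes.tsv).

    Returns the directory written to. Raises ``ValueError`` on an empty
    matrix (zero genes or zero cells); an all-zero matrix is allowed.
    """
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValueError("refusing to write an empty (0-gene or 0-cell) matrix")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(matrix.counts.astype(np.int64))
    spio.mmwrite(outdir / "matrix.mtx", coo, field="integer")
    with open(outdir / "features.tsv", "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        for c in matrix.cell_ids:
            fh.write(f"{c}\n")
    return outdir


def read_mtx(path: str | Path) -> CountMatrix:
    """Read a MatrixMarket bundle written by :func:`write_mtx` (or cellranger).

    Raises ``FileNotFoundError`` for missing pieces and ``ValueError`` for a
    malformed header, triplet indices outside the declared dimensions,
    dimension mismatches against the sidecar files, or negative entries.
    """
    indir = Path(path)
    mtx_file = indir / "matrix.mtx"
    feat_file = indir / "features.tsv"
    bc_file = indir / "barcodes.tsv"
    for f in (mtx_file, feat_file, bc_file):
        if not f.exists():
            raise FileNotFoundError(f"missing MTX bundle member: {f}")
    try:
        mat = spio.mmread(mtx_file)
    except Exception as exc:  # scipy raises ValueError subclasses on bad input
        raise ValueError(f"malformed MatrixMarket file {mtx_file}: {exc}") from exc
    counts = np.asarray(sparse.coo_matrix(mat).todense())
    if np.any(counts < 0):
        raise ValueError("negative entries in count matrix")
    gene_ids = []
    with open(feat_file) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                gene_ids.append(line.split("\t")[0])
    cell_ids = [line.strip() for line in open(bc_file) if line.strip()]
    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix.mtx is {counts.shape} but sidecars declare "
            f"{len(gene_ids)} features x {len(cell_ids)} barcodes"
        )
    return CountMatrix(counts.astype(np.int64), gene_ids, cell_ids)
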