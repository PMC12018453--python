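"""Count-matrix I/O, quality control, species assignment and normalization.

The central container is :class:`CountMatrix`: a sparse gene x cell integer
matrix with aligned gene and cell annotation tables. QC mirrors the two
filtering regimes used for traced-neuron data: plate-based (Smart-seq2-like)
cells are dropped when they have fewer than 50,000 mapped reads, fewer than
4,000 detected genes, or more than 20% of reads mapping to mitochondria;
droplet-based (10X-like) cells are dropped below 1,000 UMIs, below 500
detected genes, or above 10% mitochondrial content. Boundary semantics are
literal: "fewer than X" removes strictly below X, "more than Y" removes
strictly above Y.

Normalization is median-of-ratios size factors (library-size fallback)
followed by log2(count / factor + 1).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "QCReport",
    "NormalizedMatrix",
    "CountMatrixError",
    "read_counts",
    "write_counts",
    "qc_filter_plate",
    "qc_filter_droplet",
    "assign_species",
    "size_factors",
    "log_normalize",
]

MITO_PREFIX = "mt-"


class CountMatrixError(ValueError):
    """Malformed count matrix or annotation tables."""


def _strip_species(gene_id: str) -> tuple[str, str]:
    """Split ``"mm:Gene"`` into ``("mm", "Gene")``; empty species if untagged."""
    if ":" in gene_id:
        species, _, name = gene_id.partition(":")
        return species, name
    return "", gene_id


@dataclass
class CountMatrix:
    """Sparse gene x cell counts with aligned gene and cell annotations.

    Parameters
    ----------
    X
        ``(n_genes, n_cells)`` sparse CSR matrix of non-negative integers.
    genes
        DataFrame indexed by unique ``gene_id`` with at least ``species``
        and ``is_mito`` columns (derived from the id if absent).
    cells
        DataFrame indexed by unique ``cell_id``; per-cell metadata such as
        ``replicate``, ``condition``, ``mapped_reads``, ``mito_reads``.
    """

    X: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if "species" not in self.genes.columns:
            self.genes = self.genes.copy()
            self.genes["species"] = [
                _strip_species(g)[0] for g in self.genes.index
            ]
        if "is_mito" not in self.genes.columns:
            self.genes = self.genes.copy()
            self.genes["is_mito"] = [
                _strip_species(g)[1].lower().startswith(MITO_PREFIX)
                for g in self.genes.index
            ]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise CountMatrixError(
                f"matrix shape {self.X.shape} does not match annotation "
                f"tables ({len(self.genes)} genes, {len(self.cells)} cells)"
            )
        if not self.genes.index.is_unique:
            raise CountMatrixError("duplicate gene_ids")
        if not self.cells.index.is_unique:
            raise CountMatrixError("duplicate cell_ids")
        if self.X.nnz:
            data = self.X.data
            if data.min() < 0:
                raise CountMatrixError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise CountMatrixError("non-integral counts")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def detected_genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.X > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        if isinstance(mask_or_ids, (list, pd.Index)):
            idx = self.cells.index.get_indexer(mask_or_ids)
            if (idx < 0).any():
                raise KeyError("unknown cell ids in subset")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return CountMatrix(
            X=self.X[:, idx], genes=self.genes.copy(), cells=self.cells.iloc[idx].copy()
        )

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = self.genes.index.get_indexer(pd.Index(gene_ids))
        if (idx < 0).any():
            raise KeyError("unknown gene ids in subset")
        return CountMatrix(
            X=self.X[idx, :], genes=self.genes.iloc[idx].copy(), cells=self.cells.copy()
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC cutoffs for plate and droplet chemistries."""

    min_mapped_reads: int = 50_000
    min_detected_genes: int = 4_000
    max_mito_fraction: float = 0.20
    min_umis: int = 1_000
    min_genes_10x: int = 500
    max_mito_10x: float = 0.10

    def __post_init__(self) -> None:
        for name in ("min_mapped_reads", "min_detected_genes", "min_umis", "min_genes_10x"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_mito_fraction", "max_mito_10x"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class QCReport:
    """Per-rule removal tallies from one QC pass."""

    n_input: int
    n_kept: int
    removed_low_depth: int
    removed_low_genes: int
    removed_high_mito: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_input",
                    "n_kept",
                    "removed_low_depth",
                    "removed_low_genes",
                    "removed_high_mito",
                ],
                "value": [
                    self.n_input,
                    self.n_kept,
                    self.removed_low_depth,
                    self.removed_low_genes,
                    self.removed_high_mito,
                ],
            }
        )


@dataclass
class NormalizedMatrix:
    """Log-scale expression: ``log_base(count / size_factor + pseudocount)``."""

    values: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame
    size_factors: np.ndarray
    pseudocount: float = 1.0
    log_base: float = 2.0

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask_or_ids) -> "NormalizedMatrix":
        if isinstance(mask_or_ids, (list, pd.Index)):
            idx = self.cells.index.get_indexer(mask_or_ids)
            if (idx < 0).any():
                raise KeyError("unknown cell ids in subset")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return NormalizedMatrix(
            values=self.values[:, idx],
            genes=self.genes.copy(),
            cells=self.cells.iloc[idx].copy(),
            size_factors=self.size_factors[idx],
            pseudocount=self.pseudocount,
            log_base=self.log_base,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_counts(cm: CountMatrix, directory: str | os.PathLike) -> None:
    """Write ``matrix.mtx`` (1-based coordinate MM), ``genes.tsv``, ``cells.tsv``."""
    os.makedirs(directory, exist_ok=True)
    coo = cm.X.tocoo()
    order = np.lexsort((coo.row, coo.col))
    triplets = pd.DataFrame(
        {
            "i": coo.row[order] + 1,
            "j": coo.col[order] + 1,
            "x": coo.data[order].astype(np.int64),
        }
    )
    with open(os.path.join(directory, "matrix.mtx"), "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{cm.n_genes} {cm.n_cells} {coo.nnz}\n")
        triplets.to_csv(fh, sep=" ", header=False, index=False)
    cm.genes.to_csv(
        os.path.join(directory, "genes.tsv"), sep="\t", index_label="gene_id"
    )
    cm.cells.to_csv(
        os.path.join(directory, "cells.tsv"), sep="\t", index_label="cell_id"
    )


def read_counts(path: str | os.PathLike, format: str = "mtx") -> CountMatrix:
    """Read a count matrix.

    ``format="mtx"``: *path* is a directory holding ``matrix.mtx`` +
    ``genes.tsv`` + ``cells.tsv`` (Matrix-Market 1-based indices converted
    to internal 0-based). ``format="tsv"``: *path* is a dense TSV with gene
    ids in the first column and cell ids in the header.
    """
    if format == "mtx":
        mtx_path = os.path.join(path, "matrix.mtx")
        try:
            X = sp.csr_matrix(scipy.io.mmread(mtx_path))
        except ValueError as exc:
            raise CountMatrixError(f"malformed Matrix-Market file: {exc}") from exc
        genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", index_col=0)
        cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t", index_col=0)
        return CountMatrix(X=X, genes=genes, cells=cells)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        X = sp.csr_matrix(df.to_numpy())
        return CountMatrix(
            X=X,
            genes=pd.DataFrame(index=pd.Index(df.index, name="gene_id")),
            cells=pd.DataFrame(index=pd.Index(df.columns, name="cell_id")),
        )
    raise ValueError(f"unknown format {format!r} (expected 'mtx' or 'tsv')")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _apply_qc(cm, depth, genes_detected, mito_frac, min_depth, min_genes, max_mito):
    fail_depth = depth < min_depth
    fail_genes = genes_detected < min_genes
    fail_mito = mito_frac > max_mito
    keep = ~(fail_depth | fail_genes | fail_mito)
    report = QCReport(
        n_input=cm.n_cells,
        n_kept=int(keep.sum()),
        removed_low_depth=int(fail_depth.sum()),
        removed_low_genes=int(fail_genes.sum()),
        removed_high_mito=int(fail_mito.sum()),
    )
    return cm.subset_cells(keep), report


def qc_filter_plate(cm: CountMatrix, t: QCThresholds | None = None):
    """Plate-chemistry QC on mapped-read metadata.

    Keeps cells with ``mapped_reads >= min_mapped_reads``, detected genes
    (count > 0) ``>= min_detected_genes`` and ``mito_reads / mapped_reads
    <= max_mito_fraction``. Returns the filtered matrix and a
    :class:`QCReport` with per-rule tallies (a cell may violate several).
    """
    t = t or QCThresholds()
    for col in ("mapped_reads", "mito_reads"):
        if col not in cm.cells.columns:
            raise CountMatrixError(f"missing cell metadata column {col!r}")
    if cm.n_cells == 0:
        return cm, QCReport(0, 0, 0, 0, 0)
    depth = cm.cells["mapped_reads"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = cm.cells["mito_reads"].to_numpy(dtype=float) / depth
    return _apply_qc(
        cm,
        depth,
        cm.detected_genes_per_cell(),
        mito_frac,
        t.min_mapped_reads,
        t.min_detected_genes,
        t.max_mito_fraction,
    )


def qc_filter_droplet(cm: CountMatrix, t: QCThresholds | None = None):
    """Droplet-chemistry QC computed from the counts themselves.

    UMI total = column sum; mitochondrial fraction = counts on mito-flagged
    genes over total counts (0 for empty cells, which fail the UMI rule).
    """
    t = t or QCThresholds()
    if cm.n_cells == 0:
        return cm, QCReport(0, 0, 0, 0, 0)
    totals = cm.counts_per_cell().astype(float)
    mito_mask = cm.genes["is_mito"].to_numpy(dtype=bool)
    mito_counts = np.asarray(cm.X[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    return _apply_qc(
        cm,
        totals,
        cm.detected_genes_per_cell(),
        mito_frac,
        t.min_umis,
        t.min_genes_10x,
        t.max_mito_10x,
    )


def assign_species(cm: CountMatrix) -> pd.Series:
    """Label each cell by the species contributing > 50% of its counts.

    Species come from gene-id prefixes ("hg:", "mm:"). A cell with no
    majority species (including empty cells) is labelled ``"ambiguous"``.
    """
    species = cm.genes["species"].to_numpy()
    tags = sorted({s for s in species if s})
    if not tags:
        raise CountMatrixError("no species tags on genes")
    totals = cm.counts_per_cell().astype(float)
    labels = np.full(cm.n_cells, "ambiguous", dtype=object)
    for tag in tags:
        tag_counts = np.asarray(cm.X[species == tag, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore"):
            frac = np.where(totals > 0, tag_counts / np.maximum(totals, 1), 0.0)
        labels[frac > 0.5] = tag
    return pd.Series(labels, index=cm.cell_ids, name="species")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors(cm: CountMatrix, method: str = "median_ratio") -> np.ndarray:
    """Per-cell depth-scaling factors, rescaled to geometric mean 1.

    ``median_ratio`` follows the median-of-ratios scheme: each cell's factor
    is the median ratio of its counts to the per-gene geometric mean,
    restricted to genes nonzero in every cell (falls back to library size if
    no such gene exists). ``library_size`` scales by total counts.
    """
    totals = cm.counts_per_cell().astype(float)
    if (totals <= 0).any():
        raise CountMatrixError("all-zero cell: size factors undefined")
    if method == "library_size":
        factors = totals
    elif method == "median_ratio":
        dense = cm.to_dense().astype(float)
        positive = (dense > 0).all(axis=1)
        if not positive.any():
            factors = totals
        else:
            logref = np.log(dense[positive]).mean(axis=1)  # log geometric mean
            ratios = np.log(dense[positive]) - logref[:, None]
            factors = np.exp(np.median(ratios, axis=0))
    else:
        raise ValueError(f"unknown method {method!r}")
    return factors / np.exp(np.mean(np.log(factors)))


def log_normalize(cm: CountMatrix, factors: np.ndarray | None = None) -> NormalizedMatrix:
    """``log2(count / size_factor + 1)``, kept sparse (zeros stay zero)."""
    if factors is None:
        factors = size_factors(cm)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (cm.n_cells,):
        raise CountMatrixError("size factors not aligned to cells")
    if (factors <= 0).any():
        raise CountMatrixError("size factors must be positive")
    scaled = cm.X.tocsc().astype(float)
    scaled = scaled @ sp.diags(1.0 / factors)
    scaled.data = np.log2(scaled.data + 1.0)
    return NormalizedMatrix(
        values=sp.csr_matrix(scaled),
        genes=cm.genes.copy(),
        cells=cm.cells.copy(),
        size_factors=factors,
    )
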