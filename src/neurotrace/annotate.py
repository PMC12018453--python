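"""Reference-based cell-type annotation and graph clustering.

Label transfer follows the nearest-centroid correlation scheme: highly
variable genes are selected in the query, each query cell is correlated
(Pearson) against every reference cell-type centroid over the shared gene
set, and the cell is assigned the type with the highest coefficient. A
second, rank-based (Spearman) annotator provides an independent call for a
concordance check. Clustering builds a shared-nearest-neighbour graph on
principal components and partitions it with Louvain modularity
maximization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_qc import NormalizedMatrix

__all__ = [
    "ReferenceAtlas",
    "Assignment",
    "find_hvgs",
    "label_transfer",
    "second_annotator",
    "concordance",
    "snn_louvain",
    "composition_table",
]

UNASSIGNABLE = "unassignable"


@dataclass
class ReferenceAtlas:
    """Centroid log-expression per cell type.

    ``centroids``: genes x types DataFrame (columns = type labels);
    ``supertypes``: optional grouping, e.g. CG-derived vs DRG-derived.
    """

    centroids: pd.DataFrame
    supertypes: dict[str, str] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.centroids.columns.is_unique:
            raise ValueError("duplicate type labels in atlas")
        if self.centroids.shape[0] == 0:
            raise ValueError("empty atlas gene universe")
        if not np.isfinite(self.centroids.to_numpy()).all():
            raise ValueError("non-finite centroid values")

    @property
    def types(self) -> list[str]:
        return list(self.centroids.columns)

    def write(self, path) -> None:
        self.centroids.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, path, supertypes=None) -> "ReferenceAtlas":
        return cls(
            centroids=pd.read_csv(path, sep="\t", index_col=0),
            supertypes=supertypes,
            source=str(path),
        )


@dataclass
class Assignment:
    """Per-cell annotation: best type, correlation, runner-up and margin."""

    table: pd.DataFrame  # index cell_id: best_type, best_corr, runner_up, margin, tied

    @property
    def labels(self) -> pd.Series:
        return self.table["best_type"]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="cell_id")


def find_hvgs(nm: NormalizedMatrix, n: int) -> list[str]:
    """Top-``n`` highly variable genes by residual from a mean-variance trend.

    Per-gene mean and variance of log expression are computed across cells;
    a second-degree polynomial of variance on mean is fitted by least
    squares and genes are ranked by (variance - fitted), descending, ties
    broken by gene_id. Mirrors trend-based HVG selection as used for
    plate-based neuron data.
    """
    if nm.n_cells < 2:
        raise ValueError("need at least 2 cells for variance estimation")
    if n > len(nm.gene_ids):
        raise ValueError(f"requested {n} HVGs from {len(nm.gene_ids)} genes")
    dense = nm.to_dense()
    mean = dense.mean(axis=1)
    var = dense.var(axis=1, ddof=1)
    if np.ptp(mean) == 0:
        resid = var - var.mean()
    else:
        # standardize the regressor: raw means can be nearly collinear with
        # their square when tightly packed, making the fit unstable
        xm = (mean - mean.mean()) / max(mean.std(), 1e-12)
        coef = np.polyfit(xm, var, deg=2)
        resid = var - np.polyval(coef, xm)
    order = pd.DataFrame({"resid": -resid, "gene": nm.gene_ids}).sort_values(
        ["resid", "gene"], kind="mergesort"
    )
    return order["gene"].head(n).tolist()


def _correlate(query: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Pearson correlation of each query column against each centroid column.

    Returns (n_cells, n_types); rows with zero query variance are NaN.
    """
    q = query - query.mean(axis=0)
    c = centroids - centroids.mean(axis=0)
    qn = np.linalg.norm(q, axis=0)
    cn = np.linalg.norm(c, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (q.T @ c) / np.outer(qn, cn)
    r[qn == 0, :] = np.nan
    return np.clip(r, -1.0, 1.0)


def _assign_from_corr(r: np.ndarray, types: list[str], cell_ids) -> Assignment:
    # deterministic tie-break: types are pre-sorted lexicographically, so the
    # first argmax is the lexicographically smallest among tied types
    order = np.argsort(types, kind="mergesort")
    types_sorted = [types[i] for i in order]
    r = r[:, order]
    rows = []
    for i in range(r.shape[0]):
        ri = r[i]
        if np.isnan(ri).all():
            rows.append((UNASSIGNABLE, np.nan, "", np.nan, False))
            continue
        best = int(np.nanargmax(ri))
        tied = bool(np.sum(ri == ri[best]) > 1)
        rest = np.delete(ri, best)
        if rest.size and not np.isnan(rest).all():
            runner = int(np.nanargmax(rest))
            runner_label = [t for j, t in enumerate(types_sorted) if j != best][runner]
            margin = float(ri[best] - rest[runner])
        else:
            runner_label, margin = "", 0.0
        rows.append((types_sorted[best], float(ri[best]), runner_label, margin, tied))
    return Assignment(
        table=pd.DataFrame(
            rows,
            columns=["best_type", "best_corr", "runner_up", "margin", "tied"],
            index=pd.Index(cell_ids, name="cell_id"),
        )
    )


def _intersection(query: NormalizedMatrix, atlas: ReferenceAtlas, hvgs) -> pd.Index:
    genes = pd.Index(sorted(set(hvgs) & set(atlas.centroids.index) & set(query.gene_ids)))
    if len(genes) < 3:
        raise ValueError(
            f"only {len(genes)} genes shared between HVGs, query and atlas (need >= 3)"
        )
    return genes


def label_transfer(query: NormalizedMatrix, atlas: ReferenceAtlas, hvgs) -> Assignment:
    """Annotate each query cell as the atlas type with the highest Pearson
    correlation over the HVG/atlas/query gene intersection.

    Cells with a constant profile over the intersection (undefined
    correlation) are labelled ``"unassignable"``. Exact correlation ties
    are broken by type-label lexicographic order and flagged.
    """
    genes = _intersection(query, atlas, hvgs)
    qi = query.genes.index.get_indexer(genes)
    q = query.to_dense()[qi, :]
    c = atlas.centroids.loc[genes].to_numpy()
    r = _correlate(q, c)
    # a constant centroid also yields NaN; treat as no evidence for that type
    return _assign_from_corr(r, atlas.types, query.cell_ids)


def second_annotator(query: NormalizedMatrix, atlas: ReferenceAtlas, hvgs) -> Assignment:
    """Independent rank-based annotator: Spearman correlation against the
    same centroids. Used to corroborate :func:`label_transfer`."""
    genes = _intersection(query, atlas, hvgs)
    qi = query.genes.index.get_indexer(genes)
    q = np.apply_along_axis(rankdata, 0, query.to_dense()[qi, :])
    c = np.apply_along_axis(rankdata, 0, atlas.centroids.loc[genes].to_numpy())
    r = _correlate(q, c)
    return _assign_from_corr(r, atlas.types, query.cell_ids)


def concordance(a: Assignment, b: Assignment) -> tuple[float, pd.DataFrame]:
    """Agreement rate and confusion table between two annotators.

    Cells labelled unassignable by either annotator are excluded from the
    rate; the confusion table includes them.
    """
    if set(a.table.index) != set(b.table.index):
        raise ValueError("annotations cover different cell sets")
    la = a.labels
    lb = b.labels.reindex(la.index)
    confusion = pd.crosstab(la, lb)
    ok = (la != UNASSIGNABLE) & (lb != UNASSIGNABLE)
    if ok.sum() == 0:
        return float("nan"), confusion
    rate = float((la[ok] == lb[ok]).mean())
    return rate, confusion


def snn_louvain(
    nm: NormalizedMatrix,
    n_pcs: int = 50,
    k: int = 10,
    seed: int = 0,
    hvgs=None,
) -> np.ndarray:
    """Cluster cells: PCA -> kNN graph -> shared-nearest-neighbour weights
    -> Louvain modularity maximization.

    Edge weight between neighbours i, j is ``|shared| / (2k - |shared|)``
    over their k-nearest-neighbour sets. Labels are 0..C-1 ordered by
    decreasing cluster size; the partition is deterministic for a given
    seed (node order is shuffled once from it).
    """
    import igraph
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    n = nm.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    X = nm.to_dense()
    if hvgs is not None:
        idx = nm.genes.index.get_indexer(pd.Index(hvgs))
        X = X[idx, :]
    X = X.T  # cells x genes
    n_pcs = min(n_pcs, min(X.shape) - 1)
    if n_pcs >= 1:
        X = PCA(n_components=n_pcs, svd_solver="full", random_state=0).fit_transform(X)
    import scipy.sparse as sp

    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, knn = nbrs.kneighbors(X)  # column 0 is the cell itself
    # cells are linked whenever their (self-inclusive) kNN sets intersect;
    # weight |shared| / (2k - |shared|)
    rows = np.repeat(np.arange(n), k + 1)
    B = sp.csr_matrix((np.ones(rows.size), (rows, knn.ravel())), shape=(n, n))
    S = sp.triu((B @ B.T).tocoo(), k=1).tocoo()
    shared = np.minimum(S.data, 2 * k - 1)
    edges = list(zip(S.row.tolist(), S.col.tolist()))
    weights = (shared / (2 * k - shared)).tolist()

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    g = igraph.Graph(
        n=n, edges=[(inv[i], inv[j]) for i, j in edges], edge_attrs={"weight": weights}
    )
    import random as _random

    igraph.set_random_number_generator(_random.Random(int(seed)))
    part = g.community_multilevel(weights="weight")
    labels_perm = np.asarray(part.membership)
    labels = labels_perm[inv]
    # relabel by decreasing size, ties by first occurrence
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return np.array([remap[l] for l in labels])


def composition_table(assign: Assignment, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-condition subtype proportions (rows sum to 1) with counts."""
    if "condition" not in cells.columns:
        raise ValueError("cells metadata lacks a 'condition' column")
    labels = assign.labels.reindex(cells.index)
    counts = pd.crosstab(cells["condition"], labels)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty condition")
    props = counts.div(counts.sum(axis=1), axis=0)
    out = pd.concat({"proportion": props, "count": counts}, axis=1)
    return out
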