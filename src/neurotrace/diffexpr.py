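"""Pseudobulk differential expression.

Cells are summed into per-replicate pseudobulk libraries so the test
operates on biological replicates rather than cells. Each gene is then fit
with a negative-binomial log-link GLM (intercept + condition indicator,
library size factors as offsets) by iteratively reweighted least squares,
with per-gene dispersions estimated by method-of-moments and shrunk toward
a fitted mean-dispersion trend. Significance is a Wald z-test on the
condition coefficient with Benjamini-Hochberg correction; the pipeline's
significance rule is padj < 0.1.

When biological replicates are unavailable, a per-cell Wilcoxon rank-sum
test (exact enumeration for small groups, tie-corrected normal
approximation otherwise) is the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io_qc import CountMatrix, NormalizedMatrix

__all__ = [
    "PseudobulkTable",
    "DEResult",
    "make_pseudobulk",
    "pseudobulk_size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "wilcoxon_de",
    "bh_adjust",
    "DEFAULT_PADJ_CUTOFF",
]

DEFAULT_PADJ_CUTOFF = 0.1
LN2 = np.log(2.0)

RESULT_COLUMNS = ["gene", "baseMean", "log2FC", "se", "stat", "pvalue", "padj", "test"]


@dataclass
class PseudobulkTable:
    """Gene x library summed counts with library metadata."""

    counts: pd.DataFrame  # genes x libraries, integer
    meta: pd.DataFrame  # index library id: condition, replicate [, subpopulation], n_cells

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("pseudobulk libraries and metadata misaligned")

    @property
    def conditions(self) -> pd.Series:
        return self.meta["condition"]


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    Column order for TSV export: gene, baseMean, log2FC, se, stat, pvalue,
    padj, test. Per-condition mean (normalized) expression is carried in
    extra ``mean_<condition>`` columns.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]  # (numerator condition, denominator condition)
    n_excluded_all_zero: int = 0

    def write(self, path) -> None:
        extra = [c for c in self.table.columns if c not in RESULT_COLUMNS]
        self.table[RESULT_COLUMNS + extra].to_csv(path, sep="\t", index=False)

    def significant(self, padj_cutoff: float = DEFAULT_PADJ_CUTOFF) -> pd.DataFrame:
        return self.table[self.table["padj"] < padj_cutoff]


def make_pseudobulk(cm: CountMatrix, group_by=("replicate", "condition")) -> PseudobulkTable:
    """Sum cell counts into one library per combination of ``group_by`` columns."""
    group_by = list(group_by)
    for col in group_by:
        if col not in cm.cells.columns:
            raise ValueError(f"grouping column {col!r} missing from cell metadata")
    keys = cm.cells[group_by].astype(str).agg("_".join, axis=1)
    lib_ids = sorted(keys.unique())
    cols, meta_rows = {}, []
    X = cm.X.tocsc()
    for lib in lib_ids:
        mask = (keys == lib).to_numpy()
        cols[lib] = np.asarray(X[:, mask].sum(axis=1)).ravel().astype(np.int64)
        first = cm.cells.loc[mask].iloc[0]
        meta_rows.append([first[c] for c in group_by] + [int(mask.sum())])
    counts = pd.DataFrame(cols, index=cm.gene_ids)
    meta = pd.DataFrame(
        meta_rows, columns=group_by + ["n_cells"], index=pd.Index(lib_ids, name="library")
    )
    return PseudobulkTable(counts=counts, meta=meta)


def pseudobulk_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors over libraries (geometric mean 1)."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        totals = mat.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    logs = np.log(mat[positive])
    ratios = logs - logs.mean(axis=1, keepdims=True)
    f = np.exp(np.median(ratios, axis=0))
    return f / np.exp(np.mean(np.log(f)))


def estimate_dispersions(
    q: np.ndarray,
    cond: np.ndarray,
    inv_sf_mean: float,
    shrinkage_weight: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene NB dispersions: method-of-moments shrunk toward a trend.

    ``q`` is normalized counts (genes x libraries), ``cond`` a boolean
    condition indicator. The raw per-gene estimate solves
    ``var(q) ~= mu * mean(1/sf) + alpha * mu^2`` from the pooled
    within-condition sample variance. The declining trend
    ``alpha(mu) = a1 + a0/mu`` is fitted by maximizing the normal-theory
    chi-square likelihood of the within-condition variances under
    ``v(mu) = mu * mean(1/sf) + alpha(mu) * mu^2``, which is robust to the
    heavy-tailed per-gene estimates. The final dispersion is
    ``w * trend + (1 - w) * raw``, floored at 1e-8. The default weight 1
    uses the trend alone: with only a handful of libraries the raw
    estimate carries so few degrees of freedom that blending it in
    destabilizes the Wald test; lower the weight only with many replicates
    or when gene-specific dispersion outliers are a concern.
    Returns (alpha_hat, alpha_raw, alpha_trend).
    """
    from scipy import optimize

    n = q.shape[1]
    mu = q.mean(axis=1)
    resid = q.copy()
    for grp in (cond, ~cond):
        if grp.sum():
            resid[:, grp] -= q[:, grp].mean(axis=1, keepdims=True)
    s2 = (resid**2).sum(axis=1) / max(n - 2, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (s2 - mu * inv_sf_mean) / np.maximum(mu, 1e-12) ** 2
    raw = np.where(np.isfinite(raw), raw, 0.0)

    ok = mu > 0
    mu_ok, s2_ok = mu[ok], s2[ok]

    def nll(theta: np.ndarray) -> float:
        a1, a0 = np.exp(theta)
        v = mu_ok * inv_sf_mean + (a1 + a0 / mu_ok) * mu_ok**2
        return float(np.sum(np.log(v) + s2_ok / v))

    fit = optimize.minimize(
        nll,
        np.log([1e-3, 1.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 500},
    )
    a1, a0 = np.exp(fit.x)
    trend = a1 + a0 / np.maximum(mu, 1e-12)
    w = shrinkage_weight
    alpha = w * trend + (1.0 - w) * raw
    return np.maximum(alpha, 1e-8), raw, trend


def _nb_irls(
    y: np.ndarray,
    cond: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-gene NB GLMs: log mu = offset + b0 + b1*cond.

    Returns (beta, se_b1) with beta of shape (G, 2). All genes share the
    two-column design, so each IRLS step is a closed-form 2x2 solve.
    """
    G, n = y.shape
    x = cond.astype(float)
    qn = y / np.exp(log_sf)
    mA = qn[:, ~cond].mean(axis=1)
    mB = qn[:, cond].mean(axis=1)
    eps = 0.5
    b0 = np.log(mA + eps)
    b1 = np.log(mB + eps) - b0
    beta = np.column_stack([b0, b1])

    for _ in range(max_iter):
        eta = log_sf[None, :] + beta[:, [0]] + beta[:, [1]] * x[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - log_sf[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        new = np.column_stack([nb0, nb1])
        new = np.clip(new, -30.0, 30.0)
        delta = np.abs(new - beta).max()
        beta = new
        if delta < tol:
            break

    eta = np.clip(log_sf[None, :] + beta[:, [0]] + beta[:, [1]] * x[None, :], -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    det = np.maximum(sw * swxx - swx**2, 1e-300)
    se_b1 = np.sqrt(sw / det)
    return beta, se_b1


def nb_wald_test(
    pb: PseudobulkTable,
    contrast: tuple[str, str] = ("tumour", "healthy"),
    shrinkage_weight: float = 1.0,
) -> DEResult:
    """Negative-binomial Wald test of ``contrast[0]`` vs ``contrast[1]``.

    Requires >= 2 libraries per condition. Genes with zero counts in every
    library are excluded before testing (and before BH, which changes the
    number of hypotheses m); the count of exclusions is recorded.
    """
    num, den = contrast
    condition = pb.conditions
    for c in (num, den):
        if (condition == c).sum() < 2:
            raise ValueError(
                f"condition {c!r} has fewer than 2 pseudobulk libraries; "
                "use the per-cell Wilcoxon fallback (wilcoxon_de) instead"
            )
    keep_libs = condition.isin([num, den]).to_numpy()
    counts = pb.counts.loc[:, keep_libs]
    cond = (condition[keep_libs] == num).to_numpy()

    nonzero = counts.sum(axis=1).to_numpy() > 0
    n_excluded = int((~nonzero).sum())
    y = counts.to_numpy(dtype=float)[nonzero]
    genes = counts.index[nonzero]

    sf = pseudobulk_size_factors(counts.loc[nonzero])
    q = y / sf[None, :]
    alpha, _, _ = estimate_dispersions(q, cond, float(np.mean(1.0 / sf)), shrinkage_weight)
    beta, se_b1 = _nb_irls(y, cond, np.log(sf), alpha)

    lfc = beta[:, 1] / LN2
    se = se_b1 / LN2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(se > 0, lfc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    padj = bh_adjust(pvalue)

    table = pd.DataFrame(
        {
            "gene": genes,
            "baseMean": q.mean(axis=1),
            "log2FC": lfc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "test": "wald",
            f"mean_{num}": q[:, cond].mean(axis=1),
            f"mean_{den}": q[:, ~cond].mean(axis=1),
        }
    ).reset_index(drop=True)
    return DEResult(table=table, contrast=contrast, n_excluded_all_zero=n_excluded)


def wilcoxon_de(
    nm: NormalizedMatrix,
    groups: pd.Series,
    contrast: tuple[str, str] = ("tumour", "healthy"),
) -> DEResult:
    """Per-cell two-sided Wilcoxon rank-sum test of ``contrast[0]`` vs
    ``contrast[1]`` on log-normalized expression.

    Exact enumeration when both groups have <= 10 cells and the gene's
    values are tie-free; tie-corrected normal approximation otherwise. The
    fold change is the difference of group mean log2 expression.
    """
    num, den = contrast
    groups = groups.reindex(nm.cell_ids)
    ia = (groups == num).to_numpy()
    ib = (groups == den).to_numpy()
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    dense = nm.to_dense()
    xa, xb = dense[:, ia], dense[:, ib]
    pvals = np.ones(dense.shape[0])
    small = ia.sum() <= 10 and ib.sum() <= 10
    for g in range(dense.shape[0]):
        a, b = xa[g], xb[g]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[g] = 1.0
            continue
        ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (small and not ties) else "asymptotic"
        pvals[g] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    lfc = xa.mean(axis=1) - xb.mean(axis=1)
    padj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "gene": nm.gene_ids,
            "baseMean": dense.mean(axis=1),
            "log2FC": lfc,
            "se": np.nan,
            "stat": np.nan,
            "pvalue": pvals,
            "padj": padj,
            "test": "wilcoxon",
            f"mean_{num}": xa.mean(axis=1),
            f"mean_{den}": xb.mean(axis=1),
        }
    ).reset_index(drop=True)
    return DEResult(table=table, contrast=contrast)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
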