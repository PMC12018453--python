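"""Seeded generators for synthetic traced-neuron and stromal datasets.

The generators emulate the structure of the study design this pipeline
targets: plate-based counts for retrogradely traced peripheral neurons with
five major subpopulations (CG1, CG2 sympathetic; NEFM, PEP, NPEP sensory)
across 2 healthy and 3 tumour replicates, and droplet-based counts for six
stromal / tumour-microenvironment cell types. Ground truth (subpopulation,
condition, planted differential genes, planted ligand-receptor shifts,
planted low-quality cells) is emitted alongside the counts so every
downstream stage can be scored exactly.

Counts are negative-binomial: ``var = mu + alpha * mu**2`` with a declining
mean-dispersion trend ``alpha(m) = a1 + a0 / m`` by default. Cell expected
values are ``base_mean * 2**(planted log2 effects) * depth_factor``, with
depth factors normalized so the expectation of a gene's count equals its
base mean times its planted fold change.

All distributional choices are synthetic stand-ins for real data, chosen to
be realistic for the assay class; none are estimates from any dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_qc import CountMatrix, QCThresholds, log_normalize, size_factors

__all__ = [
    "SimConfig",
    "DEGeneSet",
    "PlantedLR",
    "GroundTruth",
    "DEFAULT_SUBPOPS",
    "DEFAULT_TME_TYPES",
    "subpop_supertype",
    "default_de_gene_sets",
    "generate_neuron_experiment",
    "generate_reference_atlas",
    "generate_tme_experiment",
    "generate_lr_table",
    "default_lr_setup",
]

DEFAULT_SUBPOPS = ("CG1", "CG2", "NEFM", "PEP", "NPEP")
DEFAULT_TME_TYPES = ("PDAC", "epithelial", "endothelial", "immune", "CAF", "fibroblast")
N_MITO_GENES = 3


def subpop_supertype(name: str) -> str:
    """Ganglion super-type of a neuronal subpopulation (CG-derived vs DRG-derived)."""
    return "CG" if name.upper().startswith("CG") else "DRG"


@dataclass(frozen=True)
class DEGeneSet:
    """A planted condition effect: gene indices shifted by ``log2fc`` in
    tumour-condition cells of the affected subpopulations."""

    gene_indices: tuple[int, ...]
    subpops: tuple[str, ...]
    log2fc: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class PlantedLR:
    """A planted ligand-receptor shift: the TME-side gene of the pair is
    shifted by ``log2fc`` in ``receiver_cell_type`` cells of ``condition``."""

    ligand: str
    receptor: str
    receiver_cell_type: str
    condition: str = "tumour"
    log2fc: float = 2.0
    tme_side: str = "ligand"  # which gene of the pair lives on the TME side

    @property
    def tme_gene(self) -> str:
        return self.ligand if self.tme_side == "ligand" else self.receptor


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults describe one plate-based neuron run: 5 subpopulations x 5
    replicates (2 healthy + 3 tumour) x 40 cells = 1,000 cells over 6,000
    genes, with 80 markers per subpopulation elevated 4-fold (neuronal
    subtype programs are broad, and rank-based annotation leans on that
    breadth) and 10% of cells planted as low quality (alternately: depth at half the 50,000
    mapped-read QC floor, or mitochondrial fraction at 1.5x the 20% cap, so
    each QC rule is exercised). Marker genes draw elevated base means
    (log-uniform 20-200) as atlas markers are well expressed; planted DE
    genes draw base means log-uniform 1,000-4,000 so they behave like the
    robustly expressed genes the signature rules target.
    """

    n_genes: int = 6000
    n_cells_per_subpop_per_replicate: int = 40
    subpop_names: tuple[str, ...] = DEFAULT_SUBPOPS
    n_replicates_healthy: int = 2
    n_replicates_tumour: int = 3
    marker_genes_per_subpop: int = 80
    marker_log2fc: float = 2.0
    de_gene_sets: tuple[DEGeneSet, ...] = ()
    baseline_mean_distribution: tuple[float, float] = (2.0, 1.2)  # lognormal loc, scale
    marker_base_mean_range: tuple[float, float] = (20.0, 200.0)
    de_base_mean_range: tuple[float, float] = (1000.0, 4000.0)
    dispersion: tuple = ("trend", 2.0, 0.05)  # alpha(m) = a1 + a0/m, or ("constant", a)
    depth_distribution: tuple[float, float] = (13.122, 0.4)  # lognormal of mapped reads
    umi_depth_distribution: tuple[float, float] = (8.987, 0.5)  # lognormal of UMI totals
    mito_fraction_distribution: tuple[float, float] = (2.0, 38.0)  # beta a, b
    fraction_low_quality_cells: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_cells_per_subpop_per_replicate",
            "n_replicates_healthy",
            "n_replicates_tumour",
            "marker_genes_per_subpop",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0 <= self.fraction_low_quality_cells <= 1:
            raise ValueError("fraction_low_quality_cells must be in [0, 1]")
        marker_idx = set(self._marker_indices().flatten().tolist())
        de_idx: set[int] = set()
        for ds in self.de_gene_sets:
            de_idx.update(ds.gene_indices)
            unknown = set(ds.subpops) - set(self.subpop_names)
            if unknown:
                raise ValueError(f"de_gene_sets names unknown subpopulations {unknown}")
        if marker_idx & de_idx:
            raise ValueError("de_gene_sets overlap marker genes")
        n_planted = len(marker_idx) + len(de_idx)
        if self.n_genes < n_planted:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than {n_planted} planted genes"
            )

    # marker genes occupy the first blocks of the gene index space
    def _marker_indices(self) -> np.ndarray:
        m = self.marker_genes_per_subpop
        return np.arange(len(self.subpop_names) * m).reshape(len(self.subpop_names), m)

    @property
    def n_cells(self) -> int:
        return (
            len(self.subpop_names)
            * (self.n_replicates_healthy + self.n_replicates_tumour)
            * self.n_cells_per_subpop_per_replicate
        )

    @property
    def replicates(self) -> list[tuple[str, str]]:
        """(replicate id, condition) pairs, healthy first."""
        reps = [(f"H{i + 1}", "healthy") for i in range(self.n_replicates_healthy)]
        reps += [(f"T{i + 1}", "tumour") for i in range(self.n_replicates_tumour)]
        return reps

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["de_gene_sets"] = [
            {"gene_indices": list(ds.gene_indices), "subpops": list(ds.subpops), "log2fc": ds.log2fc}
            for ds in self.de_gene_sets
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["de_gene_sets"] = tuple(
            DEGeneSet(tuple(e["gene_indices"]), tuple(e["subpops"]), float(e["log2fc"]))
            for e in d.get("de_gene_sets", ())
        )
        for key in (
            "subpop_names",
            "baseline_mean_distribution",
            "marker_base_mean_range",
            "de_base_mean_range",
            "dispersion",
            "depth_distribution",
            "umi_depth_distribution",
            "mito_fraction_distribution",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def default_de_gene_sets(
    cfg_or_n_markers,
    n_down: int = 30,
    n_up: int = 20,
    n_cg_decoy: int = 10,
) -> tuple[DEGeneSet, ...]:
    """The standard planting used by the demonstration pipeline.

    Plants, immediately after the marker block: ``n_down`` genes down
    2-fold-squared (log2fc -2) in three sensory subpopulations, ``n_up``
    genes up (log2fc +2) in two subpopulations spanning both super-types,
    and ``n_cg_decoy`` genes up only in the two CG subpopulations — decoys
    that consensus-signature construction must exclude as CG-only.
    """
    if isinstance(cfg_or_n_markers, SimConfig):
        start = cfg_or_n_markers.marker_genes_per_subpop * len(cfg_or_n_markers.subpop_names)
    else:
        start = int(cfg_or_n_markers)
    i = start
    down = DEGeneSet(tuple(range(i, i + n_down)), ("NEFM", "PEP", "NPEP"), -2.0)
    i += n_down
    up = DEGeneSet(tuple(range(i, i + n_up)), ("NEFM", "PEP"), 2.0)
    i += n_up
    decoy = DEGeneSet(tuple(range(i, i + n_cg_decoy)), ("CG1", "CG2"), 2.0)
    return (down, up, decoy)


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth tables for a generated experiment."""

    cells: pd.DataFrame  # index cell_id: subpopulation, replicate, condition, is_low_quality
    genes: pd.DataFrame  # index gene_id: base_mean, is_marker_of
    de_membership: pd.DataFrame  # gene_id, subpopulation, log2fc, direction
    planted_lr: pd.DataFrame  # ligand, receptor, receiver_cell_type, condition, log2fc

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.cells.to_csv(f"{directory}/truth_cells.tsv", sep="\t", index_label="cell_id")
        self.genes.to_csv(f"{directory}/truth_genes.tsv", sep="\t", index_label="gene_id")
        self.de_membership.to_csv(f"{directory}/truth_de.tsv", sep="\t", index=False)
        self.planted_lr.to_csv(f"{directory}/truth_lr.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _alpha(cfg: SimConfig, base_mean: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion from the configured rule."""
    kind = cfg.dispersion[0]
    if kind == "constant":
        return np.full_like(base_mean, float(cfg.dispersion[1]))
    if kind == "trend":
        a0, a1 = float(cfg.dispersion[1]), float(cfg.dispersion[2])
        return a1 + a0 / np.maximum(base_mean, 1e-8)
    raise ValueError(f"unknown dispersion rule {cfg.dispersion!r}")


def _sample_nb(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) via numpy's (n, p) parameterization."""
    n = 1.0 / np.maximum(alpha, 1e-12)
    if n.ndim == 1 and mu.ndim == 2:
        n = n[:, None]
    p = n / (n + np.maximum(mu, 1e-300))
    out = np.zeros(np.broadcast_shapes(np.shape(n), mu.shape), dtype=np.int64)
    pos = np.broadcast_to(mu > 0, out.shape)
    nb = np.broadcast_to(n, out.shape)
    pb = np.broadcast_to(p, out.shape)
    out[pos] = rng.negative_binomial(nb[pos], pb[pos])
    return out


def _base_means(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Baseline per-gene means plus the marker index table."""
    loc, scale = cfg.baseline_mean_distribution
    base = rng.lognormal(loc, scale, size=cfg.n_genes)
    markers = cfg._marker_indices()
    lo, hi = cfg.marker_base_mean_range
    base[markers.flatten()] = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=markers.size)
    )
    lo, hi = cfg.de_base_mean_range
    for ds in cfg.de_gene_sets:
        idx = np.asarray(ds.gene_indices)
        base[idx] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=idx.size))
    return base, markers


def _log2fc_matrix(cfg: SimConfig, gene_ids: pd.Index) -> dict[tuple[str, str], np.ndarray]:
    """Per (subpop, condition): per-gene planted log2 effect vector."""
    markers = cfg._marker_indices()
    effects: dict[tuple[str, str], np.ndarray] = {}
    for si, sub in enumerate(cfg.subpop_names):
        for cond in ("healthy", "tumour"):
            e = np.zeros(cfg.n_genes)
            e[markers[si]] += cfg.marker_log2fc
            if cond == "tumour":
                for ds in cfg.de_gene_sets:
                    if sub in ds.subpops:
                        e[np.asarray(ds.gene_indices)] += ds.log2fc
            effects[(sub, cond)] = e
    return effects


def _plan_low_quality(rng: np.random.Generator, n_cells: int, fraction: float):
    """Exactly round(fraction * n) cells, alternating depth / mito planting."""
    n_low = int(round(fraction * n_cells))
    low_idx = np.sort(rng.choice(n_cells, size=n_low, replace=False))
    modes = np.array(["depth", "mito"])[np.arange(n_low) % 2]
    return low_idx, modes


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_neuron_experiment(cfg: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Plate-based traced-neuron counts with ground truth.

    Healthy and tumour replicates of every subpopulation; marker genes
    elevated ``marker_log2fc`` in their own subpopulation; planted DE genes
    shifted in tumour cells of their affected subpopulations; exactly
    ``round(fraction_low_quality_cells * n)`` cells planted to fail plate QC
    (depth at 50% of the mapped-read floor, or mitochondrial fraction at
    1.5x the cap, alternating), with all other cells guaranteed to pass.
    """
    rng = np.random.default_rng(cfg.seed)
    t = QCThresholds()
    base, markers = _base_means(cfg, rng)
    gene_ids = pd.Index([f"mm:g{i:05d}" for i in range(cfg.n_genes)], name="gene_id")
    effects = _log2fc_matrix(cfg, gene_ids)

    cell_rows = []
    for sub in cfg.subpop_names:
        for rep, cond in cfg.replicates:
            for j in range(cfg.n_cells_per_subpop_per_replicate):
                cell_rows.append((sub, rep, cond))
    n_cells = len(cell_rows)
    order = rng.permutation(n_cells)  # interleave so low-quality planting is unbiased
    cell_rows = [cell_rows[i] for i in order]

    loc, scale = cfg.depth_distribution
    mean_depth = np.exp(loc + scale**2 / 2)
    depth = rng.lognormal(loc, scale, size=n_cells)
    a, b = cfg.mito_fraction_distribution
    mito_frac = rng.beta(a, b, size=n_cells)

    low_idx, modes = _plan_low_quality(rng, n_cells, cfg.fraction_low_quality_cells)
    is_low = np.zeros(n_cells, dtype=bool)
    is_low[low_idx] = True
    # good cells are clamped safely inside every QC boundary so the planted
    # low-quality set is exactly the removed set
    depth[~is_low] = np.maximum(depth[~is_low], 1.3 * t.min_mapped_reads)
    mito_frac[~is_low] = np.minimum(mito_frac[~is_low], 0.9 * t.max_mito_fraction)
    for i, mode in zip(low_idx, modes):
        if mode == "depth":
            depth[i] = 0.5 * t.min_mapped_reads
            mito_frac[i] = min(mito_frac[i], 0.9 * t.max_mito_fraction)
        else:
            depth[i] = max(depth[i], 1.3 * t.min_mapped_reads)
            mito_frac[i] = 1.5 * t.max_mito_fraction

    depth_factor = depth / mean_depth
    alpha = _alpha(cfg, base)
    mu = np.empty((cfg.n_genes, n_cells))
    for c, (sub, rep, cond) in enumerate(cell_rows):
        mu[:, c] = base * np.exp2(effects[(sub, cond)]) * depth_factor[c]
    counts = _sample_nb(rng, mu, alpha)

    cells = pd.DataFrame(
        {
            "subpopulation": [r[0] for r in cell_rows],
            "replicate": [r[1] for r in cell_rows],
            "condition": [r[2] for r in cell_rows],
            "ganglion": [subpop_supertype(r[0]) for r in cell_rows],
            "mapped_reads": np.round(depth).astype(np.int64),
            "mito_reads": np.round(depth * mito_frac).astype(np.int64),
        },
        index=pd.Index([f"cell{i:04d}" for i in range(n_cells)], name="cell_id"),
    )
    cm = CountMatrix(
        X=sp.csr_matrix(counts),
        genes=pd.DataFrame(index=gene_ids),
        cells=cells,
    )

    marker_of = np.array([""] * cfg.n_genes, dtype=object)
    for si, sub in enumerate(cfg.subpop_names):
        marker_of[markers[si]] = sub
    de_rows = []
    for ds in cfg.de_gene_sets:
        for gi in ds.gene_indices:
            for sub in ds.subpops:
                de_rows.append((gene_ids[gi], sub, ds.log2fc, ds.direction))
    truth = GroundTruth(
        cells=cells[["subpopulation", "replicate", "condition"]].assign(is_low_quality=is_low),
        genes=pd.DataFrame({"base_mean": base, "is_marker_of": marker_of}, index=gene_ids),
        de_membership=pd.DataFrame(
            de_rows, columns=["gene_id", "subpopulation", "log2fc", "direction"]
        ),
        planted_lr=pd.DataFrame(
            columns=["ligand", "receptor", "receiver_cell_type", "condition", "log2fc"]
        ),
    )
    return cm, truth


def generate_reference_atlas(cfg: SimConfig, cells_per_type: int = 100):
    """Reference atlas of centroid log-expression per subpopulation.

    Freshly simulates ``cells_per_type`` healthy cells of each subpopulation
    (same base means and markers as :func:`generate_neuron_experiment` under
    the same seed) and averages their library-size log-normalized profiles.
    """
    from .annotate import ReferenceAtlas

    if cells_per_type <= 0:
        raise ValueError("cells_per_type must be positive")
    rng = np.random.default_rng(cfg.seed)
    base, markers = _base_means(cfg, rng)
    gene_ids = pd.Index([f"mm:g{i:05d}" for i in range(cfg.n_genes)], name="gene_id")
    effects = _log2fc_matrix(cfg, gene_ids)
    alpha = _alpha(cfg, base)

    atlas_rng = np.random.default_rng([cfg.seed, 7919])
    centroids = {}
    for sub in cfg.subpop_names:
        mu = (base * np.exp2(effects[(sub, "healthy")]))[:, None] * np.ones(cells_per_type)
        counts = _sample_nb(atlas_rng, mu, alpha)
        cm = CountMatrix(
            X=sp.csr_matrix(counts),
            genes=pd.DataFrame(index=gene_ids),
            cells=pd.DataFrame(
                index=pd.Index([f"{sub}_ref{i}" for i in range(cells_per_type)], name="cell_id")
            ),
        )
        nm = log_normalize(cm, size_factors(cm, method="library_size"))
        centroids[sub] = nm.to_dense().mean(axis=1)
    table = pd.DataFrame(centroids, index=gene_ids)
    supertypes = {sub: subpop_supertype(sub) for sub in cfg.subpop_names}
    return ReferenceAtlas(
        centroids=table,
        supertypes=supertypes,
        source="synthetic atlas (simulated healthy cells)",
    )


def generate_tme_experiment(
    cfg: SimConfig,
    cell_types: tuple[str, ...] = DEFAULT_TME_TYPES,
    planted_lr: tuple[PlantedLR, ...] = (),
    n_hg_genes: int = 300,
    tumour_only_types: tuple[str, ...] = ("PDAC",),
    human_types: tuple[str, ...] = ("PDAC",),
    type_jitter_log2_sd: float = 0.5,
) -> tuple[CountMatrix, GroundTruth]:
    """Droplet-based tumour-microenvironment counts with ground truth.

    The gene universe is the neuron universe (mouse, ``mm:``) extended by
    ``n_hg_genes`` human genes and species-tagged mitochondrial genes, so
    species assignment and droplet QC are exercised. Mouse stromal types
    draw 98% of their expected counts from mouse genes; ``human_types``
    (the xenograft cancer cells) draw 90% from human genes. Cell-type
    identity is modelled as per-(type, gene) lognormal expression jitter
    (``type_jitter_log2_sd`` log2 units) drawn once per type and shared by
    both conditions and all replicates — real cell types differ across the
    transcriptome, and the z-scored interaction analysis relies on that
    genuine between-type variation. Planted ligand-receptor TME-side genes
    carry no jitter (their type-specificity is exactly the planted
    condition effect) and are scaled by their log2fc in the stated receiver
    type and condition. Expected per-cell totals follow the UMI depth
    distribution; low-quality planting mirrors the neuron generator
    against droplet thresholds, with mitochondrial content realised in the
    counts themselves.
    """
    for p in planted_lr:
        if p.receiver_cell_type not in cell_types:
            raise ValueError(f"unknown cell type {p.receiver_cell_type!r} in planted_lr")
    rng = np.random.default_rng([cfg.seed, 104729])
    t = QCThresholds()
    base_mm, _ = _base_means(cfg, rng)

    mm_ids = [f"mm:g{i:05d}" for i in range(cfg.n_genes)]
    hg_ids = [f"hg:g{i:05d}" for i in range(n_hg_genes)]
    mito_ids = [f"mm:mt-{i + 1}" for i in range(N_MITO_GENES)] + [
        f"hg:mt-{i + 1}" for i in range(N_MITO_GENES)
    ]
    gene_ids = pd.Index(mm_ids + hg_ids + mito_ids, name="gene_id")
    loc, scale = cfg.baseline_mean_distribution
    base_hg = rng.lognormal(loc, scale, size=n_hg_genes)
    n_total = len(gene_ids)
    mm_slice = slice(0, cfg.n_genes)
    hg_slice = slice(cfg.n_genes, cfg.n_genes + n_hg_genes)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    planted_genes = {gene_pos[p.tme_gene] for p in planted_lr if p.tme_gene in gene_pos}
    for p in planted_lr:
        if p.tme_gene not in gene_pos:
            raise ValueError(f"planted gene {p.tme_gene!r} not in gene universe")

    # per-type expected count fractions: species mix, then type jitter
    w_mm = base_mm / base_mm.sum()
    w_hg = base_hg / base_hg.sum()
    profiles: dict[str, np.ndarray] = {}
    for ct in cell_types:
        prof = np.zeros(n_total)
        if ct in human_types:
            prof[mm_slice] = 0.10 * w_mm
            prof[hg_slice] = 0.90 * w_hg
        else:
            prof[mm_slice] = 0.98 * w_mm
            prof[hg_slice] = 0.02 * w_hg
        jitter = np.exp2(rng.normal(0.0, type_jitter_log2_sd, size=n_total))
        jitter[sorted(planted_genes)] = 1.0
        jitter[-2 * N_MITO_GENES :] = 1.0
        profiles[ct] = prof * jitter

    lr_effect: dict[tuple[str, str], np.ndarray] = {}
    for p in planted_lr:
        key = (p.receiver_cell_type, p.condition)
        e = lr_effect.setdefault(key, np.zeros(n_total))
        e[gene_pos[p.tme_gene]] += p.log2fc

    cell_rows = []
    for ct in cell_types:
        for rep, cond in cfg.replicates:
            if ct in tumour_only_types and cond != "tumour":
                continue
            for _ in range(cfg.n_cells_per_subpop_per_replicate):
                cell_rows.append((ct, rep, cond))
    n_cells = len(cell_rows)
    order = rng.permutation(n_cells)
    cell_rows = [cell_rows[i] for i in order]

    loc_u, scale_u = cfg.umi_depth_distribution
    depth = rng.lognormal(loc_u, scale_u, size=n_cells)
    a, b = cfg.mito_fraction_distribution
    mito_frac = rng.beta(a, b, size=n_cells)

    low_idx, modes = _plan_low_quality(rng, n_cells, cfg.fraction_low_quality_cells)
    is_low = np.zeros(n_cells, dtype=bool)
    is_low[low_idx] = True
    depth[~is_low] = np.maximum(depth[~is_low], 3.0 * t.min_umis)
    mito_frac[~is_low] = np.minimum(mito_frac[~is_low], 0.8 * t.max_mito_10x)
    for i, mode in zip(low_idx, modes):
        if mode == "depth":
            depth[i] = 0.45 * t.min_umis
            mito_frac[i] = min(mito_frac[i], 0.8 * t.max_mito_10x)
        else:
            depth[i] = max(depth[i], 3.0 * t.min_umis)
            mito_frac[i] = 1.5 * t.max_mito_10x

    # expected count = per-type count fraction x planted fold change x depth
    mu = np.empty((n_total, n_cells))
    for c, (ct, rep, cond) in enumerate(cell_rows):
        prof = profiles[ct]
        e = lr_effect.get((ct, cond))
        if e is not None:
            prof = prof * np.exp2(e)
        mu[:, c] = prof * depth[c]
    base_all = np.concatenate([base_mm, base_hg, np.full(2 * N_MITO_GENES, 50.0)])
    alpha = _alpha(cfg, base_all)
    counts = _sample_nb(rng, mu, alpha)
    counts[-2 * N_MITO_GENES :, :] = 0

    # realise the target mitochondrial fraction in species-matched mito genes
    rest = counts.sum(axis=0)
    mito_total = np.round(mito_frac / (1.0 - mito_frac) * rest).astype(np.int64)
    for c, (ct, rep, cond) in enumerate(cell_rows):
        off = n_total - 2 * N_MITO_GENES + (N_MITO_GENES if ct in human_types else 0)
        if mito_total[c] > 0:
            counts[off : off + N_MITO_GENES, c] = rng.multinomial(
                mito_total[c], np.full(N_MITO_GENES, 1.0 / N_MITO_GENES)
            )

    totals = counts.sum(axis=0)
    cells = pd.DataFrame(
        {
            "cell_type": [r[0] for r in cell_rows],
            "replicate": [r[1] for r in cell_rows],
            "condition": [r[2] for r in cell_rows],
            "umi_total": totals,
        },
        index=pd.Index([f"tme{i:04d}" for i in range(n_cells)], name="cell_id"),
    )
    cm = CountMatrix(X=sp.csr_matrix(counts), genes=pd.DataFrame(index=gene_ids), cells=cells)
    truth = GroundTruth(
        cells=cells[["cell_type", "replicate", "condition"]]
        .rename(columns={"cell_type": "subpopulation"})
        .assign(is_low_quality=is_low),
        genes=pd.DataFrame({"base_mean": base_all, "is_marker_of": ""}, index=gene_ids),
        de_membership=pd.DataFrame(columns=["gene_id", "subpopulation", "log2fc", "direction"]),
        planted_lr=pd.DataFrame(
            [
                (p.ligand, p.receptor, p.receiver_cell_type, p.condition, p.log2fc)
                for p in planted_lr
            ],
            columns=["ligand", "receptor", "receiver_cell_type", "condition", "log2fc"],
        ),
    )
    return cm, truth


def default_lr_setup(
    cfg: SimConfig,
    neuron_truth: GroundTruth,
    n_pairs: int = 40,
    n_program: int = 20,
    program_log2fc: float = 2.0,
    receiver: str = "CAF",
) -> tuple[pd.DataFrame, tuple[PlantedLR, ...]]:
    """Ligand-receptor table plus planted shifts for the demonstration run.

    Emulates the study condition in which cancer-associated fibroblasts are
    the dominant neuronal interaction partners: ``n_program`` ligands are
    elevated 4-fold in tumour-condition cells of ``receiver``, and one
    headline pair (an Il6/Il6st-like axis) couples a CAF ligand to the most
    highly expressed available neuronal receptor so its differential score
    stands clear of the program. The gene pool is the upper half of the
    mouse gene universe, which carries no neuronal markers, no planted DE
    genes and no TME cell-type markers, keeping the planted shifts the only
    type-specific structure among the pair genes.
    """
    half = cfg.n_genes // 2
    pool = neuron_truth.genes.iloc[half:]
    ranked = pool.sort_values("base_mean", ascending=False)
    headline_receptor = ranked.index[0]  # robustly expressed neuronal receptor
    rest = [g for g in pool.index.sort_values() if g != headline_receptor]
    if 2 * n_pairs - 1 > len(rest):
        raise ValueError("gene pool too small for the requested pair count")
    rng = np.random.default_rng([cfg.seed, 15485863])
    chosen = rng.choice(len(rest), size=2 * n_pairs - 1, replace=False)
    ligands = [rest[i] for i in chosen[:n_pairs]]
    receptors = [headline_receptor] + [rest[i] for i in chosen[n_pairs:]]
    lr = pd.DataFrame(
        {
            "pair_id": [f"pair{i:03d}" for i in range(n_pairs)],
            "ligand": ligands,
            "receptor": receptors,
        }
    )
    planted = [
        PlantedLR(
            ligand=lr["ligand"][i],
            receptor=lr["receptor"][i],
            receiver_cell_type=receiver,
            condition="tumour",
            log2fc=program_log2fc,
            tme_side="ligand",
        )
        for i in range(min(n_program + 1, n_pairs))  # headline pair is i = 0
    ]
    return lr, tuple(planted)


def generate_lr_table(n_pairs: int, gene_universe, seed: int = 0) -> pd.DataFrame:
    """Random ligand-receptor pair table with disjoint ligand/receptor sets."""
    genes = list(gene_universe)
    if 2 * n_pairs > len(genes):
        raise ValueError(
            f"gene universe of {len(genes)} too small for {n_pairs} disjoint pairs"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(genes), size=2 * n_pairs, replace=False)
    ligands = [genes[i] for i in chosen[:n_pairs]]
    receptors = [genes[i] for i in chosen[n_pairs:]]
    return pd.DataFrame(
        {
            "pair_id": [f"pair{i:03d}" for i in range(n_pairs)],
            "ligand": ligands,
            "receptor": receptors,
        }
    )
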