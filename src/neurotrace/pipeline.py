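"""End-to-end orchestration: simulate/load -> QC -> normalize -> annotate ->
pseudobulk DE (per subpopulation and whole-ganglion) -> consensus signature
-> enrichment -> interaction potentials, with a run report.

Every stage writes TSV outputs under the configured output directory so
stages are independently inspectable; a fixed seed makes the whole run,
including every written table, reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import diffexpr as de
from . import enrichment as enr
from . import interactome as ia
from . import io_qc
from . import signature as sig
from . import synthetic_data as syn

__all__ = ["PipelineConfig", "RunReport", "StageError", "validate_config", "run_pipeline", "demo_config"]

log = logging.getLogger("neurotrace")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full run configuration: exactly one of ``sim`` / ``inputs`` is set.

    ``inputs`` (real-data mode) maps names to paths: ``neuron_counts``,
    ``tme_counts``, ``atlas``, ``lr_table``.
    """

    outdir: str = "neurotrace_run"
    sim: syn.SimConfig | None = None
    inputs: dict | None = None
    qc: io_qc.QCThresholds = field(default_factory=io_qc.QCThresholds)
    signature_params: sig.SignatureParams = field(default_factory=sig.SignatureParams)
    contrast: tuple[str, str] = ("tumour", "healthy")
    n_hvgs: int = 1000
    n_pcs: int = 50
    knn_k: int = 10
    padj_cutoff: float = de.DEFAULT_PADJ_CUTOFF
    n_perm: int = 1000
    lr_threshold: float = 2.0
    lr_log_base: float = 10.0
    top_k: int = 10
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim") is not None:
            d["sim"] = syn.SimConfig.from_dict(d["sim"])
        if d.get("qc") is not None:
            d["qc"] = io_qc.QCThresholds(**d["qc"])
        if d.get("signature_params") is not None:
            d["signature_params"] = sig.SignatureParams(**d["signature_params"])
        if d.get("contrast") is not None:
            d["contrast"] = tuple(d["contrast"])
        return cls(**d)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Field-named violations; an empty list means the config is valid."""
    v: list[str] = []
    if (cfg.sim is None) == (cfg.inputs is None):
        v.append("sim/inputs: exactly one of the simulation block and input paths must be set")
    if cfg.inputs is not None:
        for key in ("neuron_counts", "tme_counts", "atlas", "lr_table"):
            if key not in cfg.inputs:
                v.append(f"inputs.{key}: path missing")
    for name in ("n_hvgs", "n_pcs", "knn_k", "n_perm", "top_k"):
        if getattr(cfg, name) <= 0:
            v.append(f"{name}: must be positive")
    if not 0 < cfg.padj_cutoff <= 1:
        v.append("padj_cutoff: must be in (0, 1]")
    try:
        _ = cfg.qc, cfg.signature_params  # constructed => already validated
    except Exception as exc:  # pragma: no cover - dataclass validation raises earlier
        v.append(str(exc))
    if len(cfg.contrast) != 2 or cfg.contrast[0] == cfg.contrast[1]:
        v.append("contrast: needs two distinct condition labels")
    return v


@dataclass
class RunReport:
    """Per-stage record of inputs, parameters, outputs and counts."""

    seed: int
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def add(self, stage: str, t0: float, **info) -> None:
        rec = {"stage": stage, "wall_clock_s": round(time.perf_counter() - t0, 3), **info}
        self.stages.append(rec)
        for f in info.get("files", []):
            if f in self.outputs:
                raise RuntimeError(f"output file {f} recorded twice")
            self.outputs.append(f)

    def write(self, path) -> None:
        from . import __version__

        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "version": __version__, "stages": self.stages,
                 "outputs": self.outputs},
                fh,
                indent=2,
            )


def demo_config(seed: int = 0, outdir: str = "neurotrace_demo") -> PipelineConfig:
    """One-command synthetic demonstration configuration.

    Plants the standard differential program (30 genes down in the three
    sensory subpopulations, 20 up in two subpopulations, 10 CG-only
    decoys) so signature construction and enrichment have ground truth.
    """
    sim = syn.SimConfig(seed=seed)
    sim = dataclasses.replace(sim, de_gene_sets=syn.default_de_gene_sets(sim))
    return PipelineConfig(outdir=outdir, sim=sim, seed=seed)


def _write_tsv(df: pd.DataFrame, outdir: str, name: str, index=False, index_label=None):
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t", index=index, index_label=index_label)
    return path


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in order; any failure halts with the stage named."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    os.makedirs(cfg.outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report = RunReport(seed=cfg.seed)

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        # ---------------- inputs ----------------
        t0 = stage("inputs")
        if cfg.sim is not None:
            neurons, n_truth = syn.generate_neuron_experiment(cfg.sim)
            atlas = syn.generate_reference_atlas(cfg.sim, cells_per_type=100)
            lr, planted = syn.default_lr_setup(cfg.sim, n_truth)
            tme, t_truth = syn.generate_tme_experiment(cfg.sim, planted_lr=planted)
            files = []
            for sub, cm in (("neurons", neurons), ("tme", tme)):
                d = os.path.join(cfg.outdir, sub)
                io_qc.write_counts(cm, d)
                files += [os.path.join(d, f) for f in ("matrix.mtx", "genes.tsv", "cells.tsv")]
            atlas.write(os.path.join(cfg.outdir, "atlas.tsv"))
            ia.write_lr_table(lr, os.path.join(cfg.outdir, "lr_table.tsv"))
            n_truth.write(os.path.join(cfg.outdir, "truth_neurons"))
            t_truth.write(os.path.join(cfg.outdir, "truth_tme"))
            files += [os.path.join(cfg.outdir, "atlas.tsv"), os.path.join(cfg.outdir, "lr_table.tsv")]
        else:
            neurons = io_qc.read_counts(cfg.inputs["neuron_counts"])
            tme = io_qc.read_counts(cfg.inputs["tme_counts"])
            atlas = ann.ReferenceAtlas.read(cfg.inputs["atlas"])
            lr = ia.read_lr_table(cfg.inputs["lr_table"])
            files = []
        report.add("inputs", t0, files=files,
                   n_neurons=neurons.n_cells, n_tme_cells=tme.n_cells)

        # ---------------- qc ----------------
        t0 = stage("qc")
        neurons, plate_report = io_qc.qc_filter_plate(neurons, cfg.qc)
        tme, drop_report = io_qc.qc_filter_droplet(tme, cfg.qc)
        species = io_qc.assign_species(tme)
        f1 = _write_tsv(plate_report.to_frame(), cfg.outdir, "qc_plate.tsv")
        f2 = _write_tsv(drop_report.to_frame(), cfg.outdir, "qc_droplet.tsv")
        f3 = _write_tsv(species.to_frame(), cfg.outdir, "tme_species.tsv",
                        index=True, index_label="cell_id")
        report.add("qc", t0, files=[f1, f2, f3],
                   neurons_kept=plate_report.n_kept, tme_kept=drop_report.n_kept)

        # ---------------- normalize ----------------
        t0 = stage("normalize")
        n_factors = io_qc.size_factors(neurons)
        n_norm = io_qc.log_normalize(neurons, n_factors)
        t_norm = io_qc.log_normalize(tme, io_qc.size_factors(tme, method="library_size"))
        report.add("normalize", t0, files=[], method="median_ratio/library_size")

        # ---------------- annotate ----------------
        t0 = stage("annotate")
        hvgs = ann.find_hvgs(n_norm, min(cfg.n_hvgs, neurons.n_genes))
        primary = ann.label_transfer(n_norm, atlas, hvgs)
        secondary = ann.second_annotator(n_norm, atlas, hvgs)
        rate, confusion = ann.concordance(primary, secondary)
        clusters = ann.snn_louvain(n_norm, n_pcs=cfg.n_pcs, k=cfg.knn_k,
                                   seed=cfg.seed, hvgs=hvgs)
        primary.table["cluster"] = clusters
        composition = ann.composition_table(primary, neurons.cells)
        f1 = os.path.join(cfg.outdir, "assignments.tsv")
        primary.write(f1)
        f2 = _write_tsv(confusion, cfg.outdir, "annotator_confusion.tsv", index=True)
        f3 = _write_tsv(composition, cfg.outdir, "composition.tsv", index=True)
        report.add("annotate", t0, files=[f1, f2, f3],
                   concordance=round(rate, 4), n_clusters=int(clusters.max()) + 1)
        labels = primary.labels

        # ---------------- differential expression ----------------
        t0 = stage("de")
        cells = neurons.cells.assign(assigned=labels)
        de_results: dict[str, de.DEResult] = {}
        pop_means: dict[str, pd.Series] = {}
        files = []
        norm_counts = neurons.to_dense() / n_factors[None, :]
        runs = [("aggregate", np.ones(neurons.n_cells, dtype=bool))]
        runs += [(p, (labels == p).to_numpy()) for p in sorted(labels.unique())
                 if p != ann.UNASSIGNABLE]
        for name, mask in runs:
            sub = neurons.subset_cells(mask)
            pb = de.make_pseudobulk(sub, ("replicate", "condition"))
            try:
                res = de.nb_wald_test(pb, cfg.contrast)
            except ValueError as exc:
                log.warning("wald path unavailable for %s (%s); wilcoxon fallback", name, exc)
                res = de.wilcoxon_de(n_norm.subset_cells(mask),
                                     sub.cells["condition"], cfg.contrast)
            de_results[name] = res
            pop_means[name] = pd.Series(norm_counts[:, mask].mean(axis=1),
                                        index=neurons.gene_ids)
            files.append(os.path.join(cfg.outdir, f"de_{name}.tsv"))
            res.write(files[-1])
        report.add("de", t0, files=files,
                   genes_tested={k: len(v.table) for k, v in de_results.items()})

        # ---------------- signature ----------------
        t0 = stage("signature")
        pops = [p for p in de_results if p != "aggregate"]
        candidates = {
            p: sig.per_population_candidates(de_results[p], pop_means[p], cfg.signature_params)
            for p in pops
        }
        supertypes = {p: syn.subpop_supertype(p) for p in pops}
        signature = sig.build_consensus(candidates, supertypes, cfg.signature_params)
        f1 = os.path.join(cfg.outdir, "signature.gmt")
        sig.write_gmt(signature.as_gene_sets(), f1, description="consensus signature")
        f2 = _write_tsv(signature.provenance, cfg.outdir, "signature_provenance.tsv")
        report.add("signature", t0, files=[f1, f2],
                   n_up=len(signature.up), n_down=len(signature.down),
                   n_conflicts=len(signature.conflicts))

        # ---------------- enrichment ----------------
        t0 = stage("enrichment")
        ranked = enr.rank_genes(de_results["aggregate"])
        sets = {k: v for k, v in signature.as_gene_sets().items() if v & set(ranked.genes)}
        if sets:
            result = enr.permutation_test(ranked, sets, n_perm=cfg.n_perm, seed=cfg.seed)
            table = result.table
        else:
            log.warning("empty signature: skipping enrichment scoring")
            table = pd.DataFrame(
                columns=["set", "ES", "NES", "pval", "qval", "size", "n_absent", "leading_edge"]
            )
        f1 = _write_tsv(table, cfg.outdir, "enrichment.tsv")
        report.add("enrichment", t0, files=[f1], n_sets=len(table))

        # ---------------- interactome ----------------
        t0 = stage("interactome")
        expressed = ia.expressed_lr(neurons, neurons.cells["ganglion"], lr,
                                    threshold=cfg.lr_threshold, log_base=cfg.lr_log_base)
        potentials = ia.interaction_potential(t_norm, expressed, lr)
        pairs = ia.differential_pairs(n_norm, t_norm, lr, expressed,
                                      sender_col="ganglion", top_k=cfg.top_k)
        f1 = _write_tsv(potentials, cfg.outdir, "interaction_potentials.tsv")
        f2 = _write_tsv(pairs, cfg.outdir, "differential_pairs.tsv")
        report.add("interactome", t0, files=[f1, f2], n_pairs_ranked=len(pairs))
    except StageError:
        raise
    except Exception as exc:
        failed = report.stages[-1]["stage"] if report.stages else "inputs"
        next_stage = {
            None: "inputs", "inputs": "qc", "qc": "normalize", "normalize": "annotate",
            "annotate": "de", "de": "signature", "signature": "enrichment",
            "enrichment": "interactome",
        }.get(report.stages[-1]["stage"] if report.stages else None, "interactome")
        raise StageError(next_stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    report.write(os.path.join(cfg.outdir, "run_report.json"))
    return report
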