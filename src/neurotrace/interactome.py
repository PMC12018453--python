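"""Neuron-microenvironment ligand-receptor interaction potentials.

A ligand or receptor counts as expressed in a neuronal sender population
when the log10 of its aggregate read count (plus pseudocount 1) exceeds a
threshold (default 2). For every cognate gene — the partner, in the
ligand-receptor table, of a neuron-expressed gene — the mean log expression
per receiver cell type is z-scored across receiver types; the raw
interaction score of a receiver type is the mean of these z-scores, and the
final interaction potential subtracts the minimum raw score over the whole
comparison frame (all receiver types and both conditions of a run), so the
frame minimum is exactly 0 and conditions share a scale.

Differential pair ranking multiplies the neuron-side mean log expression of
a pair's neuronal gene by the z-scored receiver-type mean of its cognate
gene, per condition, and ranks pairs by |tumour - healthy|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import CountMatrix, NormalizedMatrix

__all__ = [
    "validate_lr_table",
    "read_lr_table",
    "write_lr_table",
    "expressed_lr",
    "interaction_potential",
    "differential_pairs",
]


def validate_lr_table(lr: pd.DataFrame) -> pd.DataFrame:
    for col in ("ligand", "receptor"):
        if col not in lr.columns:
            raise ValueError(f"ligand-receptor table lacks column {col!r}")
    if "pair_id" not in lr.columns:
        lr = lr.copy()
        lr.insert(0, "pair_id", [f"pair{i:03d}" for i in range(len(lr))])
    if lr["pair_id"].duplicated().any():
        raise ValueError("duplicate pair ids")
    if (lr["ligand"] == lr["receptor"]).any():
        raise ValueError("self-pairs in ligand-receptor table")
    return lr


def read_lr_table(path) -> pd.DataFrame:
    return validate_lr_table(pd.read_csv(path, sep="\t"))


def write_lr_table(lr: pd.DataFrame, path) -> None:
    validate_lr_table(lr).to_csv(path, sep="\t", index=False)


def expressed_lr(
    neurons: CountMatrix,
    sender_labels: pd.Series,
    lr: pd.DataFrame,
    threshold: float = 2.0,
    log_base: float = 10.0,
) -> dict[str, dict[str, set[str]]]:
    """Expressed ligand/receptor sets per neuronal sender population.

    A gene is expressed in a population iff
    ``log_base(sum of its counts across the population's cells + 1) >
    threshold``; the sets are restricted to genes appearing in the
    ligand-receptor table.
    """
    lr = validate_lr_table(lr)
    sender_labels = sender_labels.reindex(neurons.cell_ids)
    ligands = set(lr["ligand"])
    receptors = set(lr["receptor"])
    out: dict[str, dict[str, set[str]]] = {}
    for sender in sorted(sender_labels.dropna().unique()):
        mask = (sender_labels == sender).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty sender population {sender!r}")
        agg = np.asarray(neurons.X[:, mask].sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            log_agg = np.log(agg + 1.0) / np.log(log_base)
        expressed = set(neurons.gene_ids[log_agg > threshold])
        out[sender] = {
            "ligands": expressed & ligands,
            "receptors": expressed & receptors,
        }
    return out


def _cognate_genes(
    lr: pd.DataFrame, expressed: dict[str, set[str]], available: set[str]
) -> tuple[list[str], int]:
    """Receiver-side partners of neuron-expressed genes; dropped-gene count."""
    cognates: set[str] = set()
    for _, row in lr.iterrows():
        if row["ligand"] in expressed["ligands"]:
            cognates.add(row["receptor"])
        if row["receptor"] in expressed["receptors"]:
            cognates.add(row["ligand"])
    present = sorted(cognates & available)
    return present, len(cognates) - len(present)


def _zscore_across_types(means: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score over receiver types (population SD; zero var -> 0)."""
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = means.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def _type_means(
    nm: NormalizedMatrix, genes: list[str], mask_by_type: dict[str, np.ndarray]
) -> pd.DataFrame:
    gi = nm.genes.index.get_indexer(pd.Index(genes))
    dense = nm.to_dense()[gi, :]
    return pd.DataFrame(
        {t: dense[:, m].mean(axis=1) for t, m in mask_by_type.items()}, index=genes
    )


def interaction_potential(
    tme: NormalizedMatrix,
    neuron_expressed: dict[str, dict[str, set[str]]],
    lr: pd.DataFrame,
    type_col: str = "cell_type",
    replicate_col: str = "replicate",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Interaction potentials per (sender, condition, replicate, receiver type).

    Within each replicate, per-cognate-gene mean log expression is z-scored
    across the receiver cell types present in that replicate; the raw score
    of a receiver type is the mean z over cognate genes. Potentials
    subtract the minimum raw score over the sender's whole frame (every
    receiver type, replicate and condition), so each sender's frame minimum
    is exactly 0. Cognate genes absent from the TME matrix are dropped and
    counted in the ``n_dropped_genes`` column.
    """
    lr = validate_lr_table(lr)
    meta = tme.cells
    available = set(tme.gene_ids)
    rows = []
    for sender in sorted(neuron_expressed):
        genes, n_dropped = _cognate_genes(lr, neuron_expressed[sender], available)
        if not genes:
            raise ValueError(f"no cognate genes for sender {sender!r} in the TME matrix")
        raw_rows = []
        for rep in sorted(meta[replicate_col].unique()):
            rep_mask = (meta[replicate_col] == rep).to_numpy()
            cond = meta.loc[rep_mask, condition_col].iloc[0]
            types = sorted(meta.loc[rep_mask, type_col].unique())
            if len(types) < 2:
                raise ValueError(f"replicate {rep!r} has fewer than 2 receiver types")
            masks = {
                t: rep_mask & (meta[type_col] == t).to_numpy() for t in types
            }
            z = _zscore_across_types(_type_means(tme, genes, masks))
            for t in types:
                raw_rows.append((sender, cond, rep, t, float(z[t].mean())))
        frame = pd.DataFrame(
            raw_rows, columns=["sender", "condition", "replicate", "receiver_type", "raw_score"]
        )
        frame["potential"] = frame["raw_score"] - frame["raw_score"].min()
        frame["n_cognate_genes"] = len(genes)
        frame["n_dropped_genes"] = n_dropped
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def differential_pairs(
    neurons: NormalizedMatrix,
    tme: NormalizedMatrix,
    lr: pd.DataFrame,
    neuron_expressed: dict[str, dict[str, set[str]]],
    sender_col: str = "ganglion",
    type_col: str = "cell_type",
    condition_col: str = "condition",
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank ligand-receptor pairs by condition change in interaction score.

    For each sender population and each pair with a neuron-expressed side,
    score(condition, receiver type) = mean log expression of the neuronal
    gene in the sender's cells of that condition x z-scored receiver-type
    mean of the cognate gene in that condition. ``delta`` = tumour score -
    healthy score; the ``top_k`` rows per sender by |delta| are returned.
    Pairs with neither side expressed in a sender are excluded there.

    Deltas are only meaningful when both conditions are normalized over the
    same frame, so the z-scores here run across the receiver types present
    in *both* conditions (a tumour-only type such as the cancer cells
    cannot have a healthy score and would silently reshape every other
    type's z if left in one frame only).
    """
    lr = validate_lr_table(lr)
    n_meta, t_meta = neurons.cells, tme.cells
    conditions = ("healthy", "tumour")
    for cond in conditions:
        if not (n_meta[condition_col] == cond).any():
            raise ValueError(f"condition {cond!r} absent from neuron data")
        if not (t_meta[condition_col] == cond).any():
            raise ValueError(f"condition {cond!r} absent from TME data")

    tme_genes = set(tme.gene_ids)
    neuron_genes = set(neurons.gene_ids)
    n_dense = neurons.to_dense()
    common_types = sorted(
        set(t_meta.loc[(t_meta[condition_col] == "healthy").to_numpy(), type_col])
        & set(t_meta.loc[(t_meta[condition_col] == "tumour").to_numpy(), type_col])
    )
    if len(common_types) < 2:
        raise ValueError("need >= 2 receiver types present in both conditions")
    out = []
    for sender in sorted(neuron_expressed):
        expressed = neuron_expressed[sender]
        sides = []  # (pair_id, neuron_gene, tme_gene, direction)
        for _, row in lr.iterrows():
            if row["ligand"] in expressed["ligands"] and row["receptor"] in tme_genes:
                sides.append((row["pair_id"], row["ligand"], row["receptor"], "ligand->receptor"))
            if row["receptor"] in expressed["receptors"] and row["ligand"] in tme_genes:
                sides.append((row["pair_id"], row["receptor"], row["ligand"], "receptor->ligand"))
        sides = [s for s in sides if s[1] in neuron_genes]
        if not sides:
            continue
        cog_genes = sorted({s[2] for s in sides})
        scores = {}
        for cond in conditions:
            s_mask = (
                (n_meta[sender_col] == sender) & (n_meta[condition_col] == cond)
            ).to_numpy()
            if s_mask.sum() == 0:
                raise ValueError(f"no {cond} cells for sender {sender!r}")
            gi = neurons.genes.index.get_indexer(pd.Index([s[1] for s in sides]))
            neuron_side = n_dense[gi, :][:, s_mask].mean(axis=1)
            c_mask = (t_meta[condition_col] == cond).to_numpy()
            masks = {t: c_mask & (t_meta[type_col] == t).to_numpy() for t in common_types}
            z = _zscore_across_types(_type_means(tme, cog_genes, masks))
            scores[cond] = (neuron_side, z)
        nh, zh = scores["healthy"]
        nt, zt = scores["tumour"]
        for i, (pair_id, n_gene, t_gene, direction) in enumerate(sides):
            for rt in common_types:
                sh = float(nh[i] * zh.loc[t_gene, rt])
                st = float(nt[i] * zt.loc[t_gene, rt])
                out.append(
                    (sender, pair_id, n_gene, t_gene, direction, rt, sh, st, st - sh)
                )
    table = pd.DataFrame(
        out,
        columns=[
            "sender",
            "pair_id",
            "neuron_gene",
            "tme_gene",
            "direction",
            "receiver_type",
            "score_healthy",
            "score_tumour",
            "delta",
        ],
    )
    table["abs_delta"] = table["delta"].abs()
    ranked = (
        table.dropna(subset=["delta"])
        .sort_values(["sender", "abs_delta", "pair_id", "receiver_type"],
                     ascending=[True, False, True, True], kind="mergesort")
        .groupby("sender", sort=True)
        .head(top_k)
        .reset_index(drop=True)
    )
    return ranked
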