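"""Consensus up/down signature construction from per-subpopulation DE.

The membership rules mirror the cancer-nerve signature recipe: take the
top-N up- and downregulated genes per subpopulation (ranked by Wald
statistic), drop genes that are not robustly expressed (population mean
expression below a floor) or not significant enough (padj above a cap),
then keep genes recurring in at least k populations per direction
(defaults: 3 for down, 2 for up) and exclude genes whose support comes
only from CG-derived (sympathetic) populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DEResult

__all__ = [
    "SignatureParams",
    "Signature",
    "per_population_candidates",
    "build_consensus",
    "population_mean_expression",
    "write_gmt",
    "read_gmt",
]


@dataclass(frozen=True)
class SignatureParams:
    """Membership-rule parameters (defaults follow the published recipe)."""

    top_n: int = 500
    min_mean_expression: float = 500.0
    max_padj: float = 0.2
    k_down: int = 3
    k_up: int = 2
    cg_only_excluded: bool = True

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_mean_expression <= 0 or self.max_padj <= 0:
            raise ValueError("thresholds must be positive")
        if self.k_down < 1 or self.k_up < 1:
            raise ValueError("k values must be >= 1")


@dataclass
class Signature:
    """Two disjoint named gene sets with per-gene provenance."""

    name: str
    up: set[str]
    down: set[str]
    provenance: pd.DataFrame  # gene, direction, populations (comma-joined)
    params: SignatureParams
    conflicts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")

    def as_gene_sets(self) -> dict[str, set[str]]:
        return {f"{self.name}-up": set(self.up), f"{self.name}-down": set(self.down)}


def population_mean_expression(counts_dense: np.ndarray, size_factors: np.ndarray) -> np.ndarray:
    """Per-gene mean normalized count (count / size factor) across cells."""
    return (counts_dense / size_factors[None, :]).mean(axis=1)


def per_population_candidates(
    de: DEResult,
    means: pd.Series,
    p: SignatureParams | None = None,
) -> tuple[list[str], list[str]]:
    """Top-N candidate genes per direction for one subpopulation.

    Genes are ranked by the Wald statistic (descending for up, ascending
    for down, sign-restricted to the matching direction), truncated to
    ``top_n`` per direction, and then filtered: a gene is excluded when its
    mean expression in this population is below ``min_mean_expression`` or
    its padj exceeds ``max_padj``. Truncation precedes filtering.
    """
    p = p or SignatureParams()
    if means is None:
        raise ValueError("per-gene mean-expression table required")
    t = de.table.copy()
    t["mean_expr"] = t["gene"].map(means)
    if t["mean_expr"].isna().any():
        raise ValueError("mean-expression table missing genes present in the DE result")

    def _side(direction: str) -> list[str]:
        if direction == "up":
            side = t[t["stat"] > 0].sort_values(
                ["stat", "gene"], ascending=[False, True], kind="mergesort"
            )
        else:
            side = t[t["stat"] < 0].sort_values(
                ["stat", "gene"], ascending=[True, True], kind="mergesort"
            )
        side = side.head(p.top_n)
        keep = (side["mean_expr"] >= p.min_mean_expression) & (side["padj"] <= p.max_padj)
        return side.loc[keep, "gene"].tolist()

    return _side("up"), _side("down")


def build_consensus(
    candidates: dict[str, tuple[list[str], list[str]]],
    pop_supertypes: dict[str, str],
    p: SignatureParams | None = None,
    name: str = "PCN",
) -> Signature:
    """Combine per-population candidate lists into a consensus signature.

    ``candidates`` maps population -> (up list, down list). A gene enters
    the down set when it is in the down list of >= ``k_down`` populations
    (up analogously with ``k_up``); genes supported only by CG-super-type
    populations are removed; genes qualifying for both directions are
    dropped from both and recorded as conflicts. The result is invariant to
    the order populations are supplied in.
    """
    p = p or SignatureParams()
    unknown = set(candidates) - set(pop_supertypes)
    if unknown:
        raise ValueError(f"unknown population labels {sorted(unknown)}")

    support: dict[str, dict[str, list[str]]] = {"up": {}, "down": {}}
    for pop in sorted(candidates):
        up_list, down_list = candidates[pop]
        for g in up_list:
            support["up"].setdefault(g, []).append(pop)
        for g in down_list:
            support["down"].setdefault(g, []).append(pop)

    def _members(direction: str, k: int) -> dict[str, list[str]]:
        out = {}
        for g, pops in support[direction].items():
            if len(pops) < k:
                continue
            if p.cg_only_excluded and all(
                pop_supertypes[pop] == "CG" for pop in pops
            ):
                continue
            out[g] = sorted(pops)
        return out

    up = _members("up", p.k_up)
    down = _members("down", p.k_down)
    conflicts = sorted(set(up) & set(down))
    for g in conflicts:
        up.pop(g)
        down.pop(g)

    rows = [("up", g, ",".join(pops)) for g, pops in sorted(up.items())]
    rows += [("down", g, ",".join(pops)) for g, pops in sorted(down.items())]
    provenance = pd.DataFrame(rows, columns=["direction", "gene", "populations"])
    return Signature(
        name=name,
        up=set(up),
        down=set(down),
        provenance=provenance,
        params=p,
        conflicts=conflicts,
    )


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "") -> None:
    """Write gene sets in GMT format (name, description, tab-joined genes)."""
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path) -> dict[str, set[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            out[parts[0]] = {g for g in parts[2:] if g}
    return out
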