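"""Gene selection from a trained selector layer.

The first layer of a fitted model scores each input gene through the
spline weights ``w_s`` of its edges.  With a single first-layer node the
genes are globally ranked by ``|w_s|``; with several nodes the top-``t``
genes per node are pooled into an (unranked) union, since spline weights
of different nodes live on incomparable scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import KANLayerSpec

__all__ = [
    "SelectionResult",
    "rank_genes_single_node",
    "select_genes_multi_node",
    "reduce_matrix",
    "variance_rank_baseline",
    "write_gene_list",
    "read_gene_list",
]


@dataclass
class SelectionResult:
    """Selected genes, their importance scores, and how they were chosen.

    ``scores`` is empty for the multi-node union mode (no global ranking
    exists); for ranked modes it is non-increasing and matches ``genes``.
    """

    genes: list
    scores: list = field(default_factory=list)
    mode: str = "single_node_ranked"
    t_per_node: int | None = None
    g_total: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single_node_ranked", "multi_node_union",
                             "variance_ranked"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.scores and len(self.scores) != len(self.genes):
            raise ValueError("scores must match genes in length")
        self.g_total = len(self.genes)


def _ranked_top(scores: np.ndarray, g: int) -> np.ndarray:
    """Indices of the g largest scores, ties broken by ascending index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:g]


def rank_genes_single_node(layer1: KANLayerSpec, g: int,
                           gene_names: list | None = None,
                           keep: list | None = None) -> SelectionResult:
    """Rank genes by ``|w_s|`` on their single edge into the selector node.

    ``keep`` lists genes exempt from removal: they are always included
    (at their ranked positions, padding the tail if necessary) so that
    markers of small domains survive selection.
    """
    if layer1.out_dim != 1:
        raise ValueError(
            f"selector layer has {layer1.out_dim} nodes; use "
            "select_genes_multi_node for multi-node selection"
        )
    m = layer1.in_dim
    if g > m:
        raise ValueError(f"g={g} exceeds the {m} input genes")
    names = list(gene_names) if gene_names is not None else list(range(m))
    if len(names) != m:
        raise ValueError(f"gene_names must have length {m}")
    scores = np.abs(layer1.w_s[0, :])
    order = _ranked_top(scores, m)
    if keep:
        name_to_idx = {nm: i for i, nm in enumerate(names)}
        missing = [k for k in keep if k not in name_to_idx]
        if missing:
            raise KeyError(f"keep-list genes not among inputs: {missing}")
        keep_idx = {name_to_idx[k] for k in keep}
        sel = sorted(set(order[:g].tolist()) | keep_idx,
                     key=lambda i: (-scores[i], i))
    else:
        sel = list(order[:g])
    return SelectionResult(
        genes=[names[i] for i in sel],
        scores=[float(scores[i]) for i in sel],
        mode="single_node_ranked",
    )


def select_genes_multi_node(layer1: KANLayerSpec, t: int,
                            gene_names: list | None = None) -> SelectionResult:
    """Union of the per-node top-``t`` genes by ``|w_s|`` (unranked)."""
    if layer1.out_dim == 1:
        raise ValueError(
            "selector layer has a single node; use rank_genes_single_node"
        )
    m = layer1.in_dim
    if t > m:
        raise ValueError(f"t={t} exceeds the {m} input genes")
    names = list(gene_names) if gene_names is not None else list(range(m))
    if len(names) != m:
        raise ValueError(f"gene_names must have length {m}")
    union: set[int] = set()
    for node in range(layer1.out_dim):
        scores = np.abs(layer1.w_s[node, :])
        union.update(_ranked_top(scores, t).tolist())
    idx = sorted(union)
    return SelectionResult(
        genes=[names[i] for i in idx],
        scores=[],
        mode="multi_node_union",
        t_per_node=t,
    )


def reduce_matrix(X: np.ndarray, sel: SelectionResult,
                  gene_names: list) -> np.ndarray:
    """Column subset of ``X`` in ``sel.genes`` order."""
    X = np.asarray(X)
    if X.shape[1] != len(gene_names):
        raise ValueError(
            f"matrix has {X.shape[1]} columns but {len(gene_names)} gene names"
        )
    name_to_idx = {nm: i for i, nm in enumerate(gene_names)}
    missing = [g for g in sel.genes if g not in name_to_idx]
    if missing:
        raise KeyError(f"selected genes absent from the matrix: {missing}")
    cols = [name_to_idx[g] for g in sel.genes]
    return X[:, cols]


def variance_rank_baseline(X: np.ndarray, g: int,
                           gene_names: list | None = None) -> SelectionResult:
    """Rank genes by per-gene variance of the (log-scale) matrix; top g."""
    X = np.asarray(X, dtype=np.float64)
    m = X.shape[1]
    if g > m:
        raise ValueError(f"g={g} exceeds the {m} genes")
    names = list(gene_names) if gene_names is not None else list(range(m))
    var = X.var(axis=0)
    idx = _ranked_top(var, g)
    return SelectionResult(
        genes=[names[i] for i in idx],
        scores=[float(var[i]) for i in idx],
        mode="variance_ranked",
    )


def write_gene_list(sel: SelectionResult, path) -> None:
    """Two-column delimited file: gene name, score (NA when unranked)."""
    with open(path, "w") as fh:
        fh.write(f"# mode={sel.mode}\tt_per_node={sel.t_per_node}\n")
        for i, gene in enumerate(sel.genes):
            score = repr(sel.scores[i]) if sel.scores else "NA"
            fh.write(f"{gene}\t{score}\n")


def read_gene_list(path) -> SelectionResult:
    genes, scores = [], []
    mode, t_per_node = "single_node_ranked", None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].split("\t"):
                    key, _, val = part.strip().partition("=")
                    if key == "mode":
                        mode = val
                    elif key == "t_per_node" and val != "None":
                        t_per_node = int(val)
                continue
            gene, _, score = line.partition("\t")
            genes.append(gene)
            if score != "NA":
                scores.append(float(score))
    return SelectionResult(genes=genes, scores=scores, mode=mode,
                           t_per_node=t_per_node)
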