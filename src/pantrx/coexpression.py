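"""Coexpression network construction and topological-overlap modules.

The network keeps gene pairs with |Pearson r| >= 0.67 and recursively
prunes nodes of degree < 5 until a fixed point.  Modules are detected on
the signed topological overlap matrix (soft power beta = 5) by
average-linkage hierarchical clustering with a static tree cut, and
pre-modules whose eigengenes are nearly collinear (correlation
dissimilarity < 0.2) are merged iteratively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "ModuleSet",
    "build_network",
    "compute_tom",
    "detect_modules",
    "eigengene_summary",
]


@dataclass
class CoexpressionNetwork:
    nodes: pd.Index
    edges: pd.DataFrame  # columns gene_a, gene_b, r (unordered pairs, a < b)
    degree: pd.Series
    correlation: pd.DataFrame  # node x node signed Pearson r

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class ModuleSet:
    assignments: pd.Series  # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # module x isolate
    merge_history: List[tuple] = field(default_factory=list)

    @property
    def module_ids(self) -> list:
        return [m for m in sorted(self.assignments.unique()) if m != 0]


def build_network(
    expr: ExpressionMatrix,
    r_threshold: float = 0.67,
    min_degree: int = 5,
) -> CoexpressionNetwork:
    """Threshold the gene-gene correlation matrix and prune low-degree nodes.

    Zero-variance genes are excluded before computing correlations.  Node
    removal iterates deleting *all* nodes below ``min_degree`` simultaneously
    and recomputing degrees until no node changes, which makes the fixed
    point independent of deletion order.
    """
    if expr.n_isolates < 3:
        raise ValueError("need at least 3 isolates for correlations")
    values = expr.values
    variances = values.var(axis=1)
    dropped = variances.index[variances == 0]
    if len(dropped):
        logger.warning("excluding %d zero-variance genes", len(dropped))
        values = values.drop(index=dropped)
    genes = values.index
    corr = np.corrcoef(values.to_numpy())
    np.fill_diagonal(corr, 0.0)
    adj = np.abs(corr) >= r_threshold

    keep = np.ones(len(genes), dtype=bool)
    while True:
        degree = (adj & keep[None, :] & keep[:, None]).sum(axis=1)
        low = keep & (degree < min_degree)
        if not low.any():
            break
        keep &= ~low

    node_idx = np.flatnonzero(keep)
    nodes = genes[node_idx]
    sub_corr = corr[np.ix_(node_idx, node_idx)]
    sub_adj = adj[np.ix_(node_idx, node_idx)]
    ia, ib = np.nonzero(np.triu(sub_adj, k=1))
    edges = pd.DataFrame(
        {
            "gene_a": nodes[ia],
            "gene_b": nodes[ib],
            "r": sub_corr[ia, ib],
        }
    )
    degree = pd.Series(sub_adj.sum(axis=1), index=nodes, name="degree")
    corr_df = pd.DataFrame(sub_corr, index=nodes, columns=nodes)
    np.fill_diagonal(corr_df.values, 1.0)
    return CoexpressionNetwork(nodes=nodes, edges=edges, degree=degree, correlation=corr_df)


def compute_tom(correlation: pd.DataFrame, beta: int = 5):
    """Signed-adjacency topological overlap from a correlation matrix.

    a_ij = ((1 + r_ij) / 2) ** beta, and

        TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with k_i the sum of a_iu over u != i, TOM_ii = 1.  Returns
    (similarity, dissimilarity = 1 - similarity) as DataFrames.
    """
    corr = np.asarray(correlation, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    a = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    index = correlation.index if isinstance(correlation, pd.DataFrame) else None
    tom_df = pd.DataFrame(tom, index=index, columns=index)
    return tom_df, 1.0 - tom_df


def _eigengene(module_expr: pd.DataFrame) -> pd.Series:
    """Unit-norm first principal component of a module's standardized
    expression across isolates, oriented so the mean gene-eigengene
    correlation is non-negative."""
    x = module_expr.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    # first right singular vector = PC of isolates
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    corr_sign = np.sign((z @ me).mean())
    if corr_sign < 0:
        me = -me
    return pd.Series(me, index=module_expr.columns)


def _dynamic_cut(link: np.ndarray, n: int, cut_height: float, split_gap: float):
    """Height cut with recursive gap splitting (a light dynamic tree cut).

    Merges above ``cut_height`` always split.  A merge at or below the cut
    still splits when its height exceeds the internal merge heights of its
    children by more than ``split_gap`` — the signature of two tight
    branches joined near the cut.  Over-splitting is harmless here because
    near-collinear pre-modules are re-fused by eigengene merging.
    """
    heights = link[:, 2]
    labels = np.zeros(n, dtype=int)
    next_label = [0]

    def node_height(node: int) -> float:
        return heights[node - n] if node >= n else 0.0

    def leaves(node: int, out: list) -> None:
        if node < n:
            out.append(node)
        else:
            leaves(int(link[node - n, 0]), out)
            leaves(int(link[node - n, 1]), out)

    def assign(node: int) -> None:
        next_label[0] += 1
        idx: list = []
        leaves(node, idx)
        labels[idx] = next_label[0]

    # local gap of a merge: its height above the tallest internal child;
    # a pair of leaves has gap 0.  needs_split propagates bottom-up so a
    # big jump anywhere inside a subtree splits it from the top.
    needs_split = np.zeros(2 * n - 1, dtype=bool)
    for m in range(n - 1):
        node = n + m
        left, right = int(link[m, 0]), int(link[m, 1])
        internal_child_h = [node_height(c) for c in (left, right) if c >= n]
        gap = heights[m] - max(internal_child_h) if internal_child_h else 0.0
        needs_split[node] = (
            heights[m] > cut_height
            or gap > split_gap
            or needs_split[left]
            or needs_split[right]
        )

    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            assign(node)
        elif needs_split[node]:
            stack.extend((int(link[node - n, 0]), int(link[node - n, 1])))
        else:
            assign(node)
    return labels


def detect_modules(
    tom_dissim: pd.DataFrame,
    expr: ExpressionMatrix,
    cut_height: float = 0.95,
    min_cluster_size: int = 5,
    merge_dissim: float = 0.2,
    split_gap: float = 0.15,
) -> ModuleSet:
    """Average-linkage clustering on TOM dissimilarity + eigengene merging.

    The tree is cut at ``cut_height`` with recursive gap splitting (see
    :func:`_dynamic_cut`); clusters below ``min_cluster_size`` leave their
    genes unassigned (module 0).  Pre-module eigengenes are then merged
    greedily: while the closest pair of eigengenes has correlation
    dissimilarity (1 - r) below ``merge_dissim``, the pair is fused and
    eigengenes recomputed.  Final modules are renumbered by decreasing size.
    """
    d = np.asarray(tom_dissim, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("tom_dissim must be square symmetric")
    genes = tom_dissim.index
    condensed = squareform((d + d.T) / 2.0, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    labels = _dynamic_cut(link, len(genes), cut_height, split_gap)

    assignments = pd.Series(labels, index=genes)
    sizes = assignments.value_counts()
    small = sizes.index[sizes < min_cluster_size]
    assignments[assignments.isin(small)] = 0
    module_ids = [m for m in sorted(assignments.unique()) if m != 0]
    if len(module_ids) == 1:
        logger.warning("all genes fell into a single module at cut height %.2f", cut_height)

    expr_vals = expr.values.loc[genes]
    eigengenes = {
        m: _eigengene(expr_vals.loc[assignments.index[assignments == m]])
        for m in module_ids
    }
    merge_history: List[tuple] = []
    while len(eigengenes) > 1:
        ids = sorted(eigengenes)
        me = np.vstack([eigengenes[m].to_numpy() for m in ids])
        cor = np.corrcoef(me)
        dis = 1.0 - cor
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= merge_dissim:
            break
        # merge lexicographically smallest pair id wins
        keep_id, drop_id = sorted((ids[i], ids[j]))
        assignments[assignments == drop_id] = keep_id
        merge_history.append((drop_id, keep_id, float(dis[i, j])))
        del eigengenes[drop_id]
        eigengenes[keep_id] = _eigengene(
            expr_vals.loc[assignments.index[assignments == keep_id]]
        )

    # renumber by decreasing module size
    final_sizes = assignments[assignments != 0].value_counts()
    order = sorted(final_sizes.index, key=lambda m: (-final_sizes[m], m))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    assignments = assignments.map(lambda m: relabel.get(m, 0))
    eigengene_df = pd.DataFrame(
        {relabel[m]: eigengenes[m] for m in order}
    ).T.sort_index()
    eigengene_df.index.name = "module"
    return ModuleSet(
        assignments=assignments, eigengenes=eigengene_df, merge_history=merge_history
    )


def eigengene_summary(modules: ModuleSet):
    """Pairwise eigengene similarity and a 2-PC projection of isolates.

    Returns (similarity DataFrame, isolate coordinates on PC1/PC2,
    variance-explained fractions per PC).
    """
    me = modules.eigengenes
    if me.shape[0] < 1:
        raise ValueError("no modules")
    if me.shape[0] == 1:
        similarity = pd.DataFrame([[1.0]], index=me.index, columns=me.index)
    else:
        similarity = pd.DataFrame(
            np.corrcoef(me.to_numpy()), index=me.index, columns=me.index
        )
    x = me.to_numpy().T  # isolates x modules
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / max(len(x) - 1, 1)
    explained = var / var.sum() if var.sum() > 0 else var
    n_pc = min(2, u.shape[1])
    coords = pd.DataFrame(
        u[:, :n_pc] * s[:n_pc],
        index=me.columns,
        columns=[f"PC{i + 1}" for i in range(n_pc)],
    )
    return similarity, coords, explained[:n_pc]
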