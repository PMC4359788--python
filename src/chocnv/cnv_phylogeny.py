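"""CNV-count distances between genomes and neighbor-joining trees.

The distance between two genomes is the number of genes whose normalized
depths differ by more than 0.95 — an integer gene count.  It is symmetric
with zero diagonal but is a premetric only: the triangle inequality can
fail (two genomes may each differ from a third in disjoint gene sets),
which neighbor joining tolerates.

Neighbor joining follows the classic Saitou-Nei agglomeration: minimize
Q(i,j) = (n-2) d(i,j) - r_i - r_j, join the pair, compute branch lengths
from the row sums, and reduce the matrix.  Ties in Q break to the smallest
(row, column) index pair after lexicographic label sort, the joined node
inheriting the smaller row; negative branch lengths are clamped to zero
with the deficit moved to the sibling branch.  Bootstrap resamples genes
(the exchangeable unit of the distance) with replacement and summarizes
replicates as the majority-rule (>50%) consensus with support percentages.
"""

from __future__ import annotations

from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .depth_profiling import GeneDepthTable


def cnv_distance(
    table_a: GeneDepthTable, table_b: GeneDepthTable, cnv_diff: float = 0.95
) -> int:
    """Number of genes with |normalized_a - normalized_b| > cnv_diff."""
    a, b = table_a.normalized, table_b.normalized
    if set(a.index) != set(b.index):
        raise ValueError("gene universes differ")
    # strict inequality, robust to binary representation of the threshold
    return int((np.abs(a - b.reindex(a.index)) > cnv_diff + 1e-9).sum())


def _depth_matrix(
    tables: Mapping[str, GeneDepthTable], exclude_always_zero: bool = True
) -> pd.DataFrame:
    """Samples x genes matrix of normalized depths on the common universe."""
    frame = pd.DataFrame({s: t.normalized for s, t in tables.items()}).T
    if frame.isna().any().any():
        raise ValueError("gene universes differ between samples")
    if exclude_always_zero:
        frame = frame.loc[:, (frame > 0.05).any(axis=0)]
    return frame.sort_index()


def distance_matrix(
    tables: Mapping[str, GeneDepthTable],
    cnv_diff: float = 0.95,
    exclude_always_zero: bool = True,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise CNV gene counts.

    Genes at ~0 normalized depth in every sample carry no information about
    relatedness (they cannot differ) and are excluded by default.
    """
    frame = _depth_matrix(tables, exclude_always_zero)
    values = frame.to_numpy()
    n = len(frame)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = int((np.abs(values[i] - values[j]) > cnv_diff + 1e-9).sum())
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=frame.index, columns=frame.index)


def neighbor_joining(matrix: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Deterministic: taxa are processed in lexicographic label order and Q
    ties break to the smallest index pair.  Requires >= 3 taxa.
    """
    labels = sorted(matrix.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if list(matrix.index) != list(matrix.columns):
        raise ValueError("matrix rows and columns must match")
    d = matrix.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("matrix must be symmetric")

    subtrees = [_quote(label) for label in labels]
    while len(subtrees) > 3:
        n = len(subtrees)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for i in range(n):
            for j in range(i + 1, n):
                if q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        merged = f"({subtrees[i]}:{_fmt(li)},{subtrees[j]}:{_fmt(lj)})"
        new_row = (d[i] + d[j] - d[i, j]) / 2
        new_row = np.maximum(new_row, 0.0)
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.empty((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d_new[-1, -1] = 0.0
        subtrees = [subtrees[k] for k in keep] + [merged]
        d = d_new

    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = d[0, 1] - la
    lc = d[0, 2] - la
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = (
        f"({subtrees[0]}:{_fmt(la)},{subtrees[1]}:{_fmt(lb)},{subtrees[2]}:{_fmt(lc)});"
    )
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'" if any(c in label for c in " ()[]:;,'") else label


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative length clamped to 0, deficit moved to the sibling branch
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def bootstrap_consensus(
    tables: Mapping[str, GeneDepthTable],
    n_replicates: int = 100,
    seed: int = 0,
    cnv_diff: float = 0.95,
    exclude_always_zero: bool = True,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Majority-rule consensus of NJ trees over gene-resampled replicates.

    Each replicate resamples the gene columns with replacement, recomputes
    every pairwise CNV distance and the NJ tree.  Returns the consensus
    tree, whose internal-node labels carry support as the percentage of
    replicates containing the bipartition, together with the full-data
    distance matrix.
    """
    frame = _depth_matrix(tables, exclude_always_zero)
    labels = list(frame.index)
    values = frame.to_numpy()
    n_samples, n_genes = values.shape
    # boolean CNV indicator per pair and gene: distance = indicator @ counts
    pairs = [(i, j) for i in range(n_samples) for j in range(i + 1, n_samples)]
    indicator = np.stack(
        [np.abs(values[i] - values[j]) > cnv_diff + 1e-9 for i, j in pairs]
    ).astype(np.float64)

    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=taxa)
    for _ in range(n_replicates):
        draws = rng.integers(0, n_genes, size=n_genes)
        counts = np.bincount(draws, minlength=n_genes).astype(np.float64)
        dist = indicator @ counts
        mat = np.zeros((n_samples, n_samples))
        for (i, j), dval in zip(pairs, dist):
            mat[i, j] = mat[j, i] = dval
        tree = neighbor_joining(pd.DataFrame(mat, index=labels, columns=labels))
        trees.append(
            dendropy.Tree.get(
                data=tree.as_string(schema="newick", unquoted_underscores=True),
                schema="newick",
                taxon_namespace=taxa,
                preserve_underscores=True,
            )
        )
    consensus = trees.consensus(min_freq=0.5)
    consensus.encode_bipartitions()
    for t in trees:
        t.encode_bipartitions()
    for edge in consensus.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or node.parent_node is None:
            continue
        freq = trees.frequency_of_bipartition(
            split_bitmask=edge.bipartition.split_bitmask
        )
        node.label = f"{freq * 100:.0f}"
    full_matrix = distance_matrix(tables, cnv_diff, exclude_always_zero)
    return consensus, full_matrix


def support_of_pair(tree: dendropy.Tree, label_a: str, label_b: str) -> float | None:
    """Support (%) of the bipartition splitting two leaves from the rest,
    or None if the tree does not contain it."""
    taxa = frozenset((label_a, label_b))
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    for node in tree.internal_nodes():
        leaf_labels = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if leaf_labels == taxa or all_leaves - leaf_labels == taxa:
            return float(node.label) if node.label is not None else 100.0
    return None


def has_bipartition(tree: dendropy.Tree, labels: set[str]) -> bool:
    """Whether the (unrooted) tree separates ``labels`` from the rest."""
    target = frozenset(labels)
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    for node in tree.internal_nodes():
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if side == target or all_leaves - side == target:
            return True
    return False
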