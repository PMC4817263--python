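"""Shared tree helpers: patristic distances, edge tables, depth counts.

Trees are :class:`dendropy.Tree` objects throughout the package; these
helpers expose the few traversal products the statistics need as plain
numpy/pandas structures so the numerical code never walks a tree itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

__all__ = [
    "tip_labels",
    "patristic_matrix",
    "edge_table",
    "ancestor_counts",
    "total_branch_length",
]


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's own (postorder leaf) order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """All tip-pair path-length sums as a symmetric labelled DataFrame.

    Computed by a single postorder pass: each node carries the distances from
    itself to the tips below it, and tip pairs are charged where their paths
    first join.  Raises ``ValueError`` on a missing branch length.
    """
    labels = tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    dist = np.zeros((n, n))
    below: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = (
                np.array([index[node.taxon.label]]), np.zeros(1))
            continue
        groups = []
        for child in node.child_nodes():
            if child.edge.length is None:
                raise ValueError("tree has a missing branch length")
            idx, d = below.pop(id(child))
            groups.append((idx, d + child.edge.length))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ia, da = groups[i]
                ib, db = groups[j]
                pair = da[:, None] + db[None, :]
                dist[np.ix_(ia, ib)] = pair
                dist[np.ix_(ib, ia)] = pair.T
        below[id(node)] = (
            np.concatenate([g[0] for g in groups]),
            np.concatenate([g[1] for g in groups]))
    return pd.DataFrame(dist, index=labels, columns=labels)


def edge_table(tree: dendropy.Tree) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Branch lengths and tip incidence for every non-root edge.

    Returns ``(lengths, incidence, labels)`` where ``incidence[e, t]`` is True
    when tip ``t`` lies below edge ``e``.  This is the workhorse for Faith PD
    and UniFrac: any statistic of the form "sum branch lengths over edges
    whose subtree intersects a taxon set" becomes a boolean matrix product.
    """
    labels = tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask = np.zeros(len(labels), dtype=bool)
            mask[index[node.taxon.label]] = True
        else:
            mask = np.zeros(len(labels), dtype=bool)
            for child in node.child_nodes():
                mask |= below.pop(id(child))
        below[id(node)] = mask
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("tree has a missing branch length")
        lengths.append(node.edge.length)
        rows.append(mask)
    return np.asarray(lengths), np.asarray(rows), labels


def ancestor_counts(tree: dendropy.Tree) -> pd.Series:
    """Number of nodes separating each tip from the root (root counted).

    Equivalently the number of edges on the tip-to-root path; used for the
    mean-root-distance statistic.
    """
    counts = {}
    for leaf in tree.leaf_node_iter():
        depth = 0
        node = leaf.parent_node
        while node is not None:
            depth += 1
            node = node.parent_node
        counts[leaf.taxon.label] = depth
    return pd.Series(counts, name="root_distance")


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(node.edge.length or 0.0
               for node in tree.preorder_node_iter()
               if node is not tree.seed_node)
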