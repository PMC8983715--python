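"""Neighbor-joining tree construction and branch-representative picking.

The cross-strategy comparison places candidate aptamers from both selection
routes on one neighbor-joining (Saitou-Nei) tree built from alignment
distances; the main branches are then summarized by their most frequent
leaf, reproducing the "pick one representative per branch" step that turns
a tree of ~80 candidates into a short list for empirical testing.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = ["nj_tree", "pick_representatives", "tree_to_newick"]


def _validate(dist: np.ndarray, labels: list[str]) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 2:
        raise ValueError("need at least two taxa")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return dist


def nj_tree(labels: list[str], dist: np.ndarray) -> TreeNode:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Negative branch lengths (possible on non-additive data) are clamped to
    zero.  The unrooted topology is serialized rooted at the last join; on
    additive distances NJ recovers the generating tree exactly.  ``n = 2``
    returns the single edge split evenly.
    """
    dist = _validate(dist, labels)
    if len(labels) == 2:
        half = dist[0, 1] / 2.0
        tips = [TreeNode(name=labels[0], length=half),
                TreeNode(name=labels[1], length=half)]
        return TreeNode(children=tips)
    dm = DistanceMatrix(dist, labels)
    return _skbio_nj(dm, neg_as_zero=True)


def _leaf_components(edges, leaves, removed):
    """Connected components of the leaf set after edge removal (union-find)."""
    parent: dict[int, int] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (u, v, _w, idx) in edges:
        if idx in removed:
            continue
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[int, list[str]] = {}
    for node_id, name in leaves:
        comps.setdefault(find(node_id), []).append(name)
    return list(comps.values())


def pick_representatives(tree: TreeNode, k: int, freq: dict[str, float]) -> list[str]:
    """Cut the tree into ``k`` clades and return each clade's most frequent
    leaf.

    Greedy longest-edge removal: the ``k - 1`` longest edges are removed
    (ties broken by traversal order), splitting the tree into ``k`` leaf
    groups; within each group the leaf with the highest frequency wins,
    ties by lexicographic sequence.  Results are sorted by representative
    frequency descending.  ``k >= number of leaves`` returns all leaves.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    node_id = {id(n): i for i, n in enumerate(tree.traverse(include_self=True))}
    edges = []
    leaves = []
    for n in tree.traverse(include_self=True):
        if n.parent is not None:
            w = n.length if n.length is not None else 0.0
            edges.append((node_id[id(n.parent)], node_id[id(n)], w, len(edges)))
        if n.is_tip():
            leaves.append((node_id[id(n)], n.name))
    n_leaves = len(leaves)
    if k >= n_leaves:
        return sorted((name for _, name in leaves),
                      key=lambda s: (-freq.get(s, 0.0), s))
    by_len = sorted(edges, key=lambda e: (-e[2], e[3]))
    removed = set()
    for e in by_len:
        if len(removed) == k - 1:
            break
        # only cuts that actually split the current leaf partition count
        trial = removed | {e[3]}
        if len(_leaf_components(edges, leaves, trial)) > len(_leaf_components(edges, leaves, removed)):
            removed = trial
    comps = _leaf_components(edges, leaves, removed)
    reps = []
    for comp in comps:
        reps.append(min(comp, key=lambda s: (-freq.get(s, 0.0), s)))
    return sorted(reps, key=lambda s: (-freq.get(s, 0.0), s))


def tree_to_newick(tree: TreeNode) -> str:
    return str(tree).strip()
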