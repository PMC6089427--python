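"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, graph searches,
forward simulation from hand-built trees) and shares no code with the
package internals it validates.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
UNAMBIGUOUS = PURINES | PYRIMIDINES


def naive_site_counts(a: str, b: str) -> dict:
    """Site-pattern counts by explicit per-site enumeration."""
    assert len(a) == len(b)
    n = ts_ag = ts_ct = tv = 0
    bases = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(a.upper(), b.upper()):
        if x not in UNAMBIGUOUS or y not in UNAMBIGUOUS:
            continue
        n += 1
        bases[x] += 1
        bases[y] += 1
        if x == y:
            continue
        if {x, y} == PURINES:
            ts_ag += 1
        elif {x, y} == PYRIMIDINES:
            ts_ct += 1
        else:
            tv += 1
    return {
        "n_sites": n,
        "n_ts_AG": ts_ag,
        "n_ts_CT": ts_ct,
        "n_tv": tv,
        "base_counts": (bases["A"], bases["C"], bases["G"], bases["T"]),
    }


def naive_components(labels, data: np.ndarray, cutoff: float) -> set[frozenset]:
    """Connected components under d < cutoff, by breadth-first search."""
    unvisited = set(range(len(labels)))
    comps = set()
    while unvisited:
        seed = min(unvisited)
        stack, comp = [seed], set()
        unvisited.discard(seed)
        while stack:
            i = stack.pop()
            comp.add(i)
            for j in list(unvisited):
                if data[i, j] < cutoff:
                    unvisited.discard(j)
                    stack.append(j)
        comps.add(frozenset(labels[i] for i in comp))
    return comps


def random_additive_tree(rng: np.random.Generator, n_leaves: int,
                         min_len: float = 0.05, max_len: float = 1.0):
    """A random binary tree with positive branch lengths and its leaf labels.

    Built by repeatedly attaching a new leaf to a uniformly chosen existing
    edge, so every topology shape is reachable.
    """
    labels = [f"t{i}" for i in range(n_leaves)]

    def blen() -> float:
        return float(rng.uniform(min_len, max_len))

    root = TreeNode()
    for name in labels[:3]:
        leaf = TreeNode(name=name)
        leaf.length = blen()
        root.append(leaf)
    for name in labels[3:]:
        edges = [n for n in root.traverse(include_self=False)]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        split = TreeNode()
        old_len = target.length
        cut = float(rng.uniform(0.2, 0.8)) * old_len
        parent.remove(target)
        target.length = old_len - cut
        split.length = cut
        split.append(target)
        leaf = TreeNode(name=name)
        leaf.length = blen()
        split.append(leaf)
        parent.append(split)
    return labels, root


def tree_distance_matrix(tree: TreeNode, labels) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of a tree (the additive matrix)."""
    tt = tree.tip_tip_distances()
    idx = {name: i for i, name in enumerate(tt.ids)}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = tt.data[idx[labels[i]], idx[labels[j]]]
    return out


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as {side, complement} pairs, by traversal."""
    taxa = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            out.add(frozenset((side, taxa - side)))
    return out
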