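"""Neighbor-joining trees, bootstrap support, rooting and monophyly tests.

Trees are ``skbio.TreeNode`` objects: leaves named by sequence ID, branch
lengths in substitutions/site, and an optional ``support`` attribute (percent
of bootstrap replicates) on internal nodes.

The NJ agglomeration is the canonical one: the pair minimizing
``Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)`` is joined, with
the rate-corrected branch split and the standard distance update
``d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2``. Ties in Q are broken by the
lexicographically smallest pair of clade representative labels (the smallest
leaf name in each clade), so topologies are reproducible. Negative branch
length estimates are clamped to zero, with the deficit shifted to the sibling
branch so path lengths are preserved.

Monophyly is assessed on a rooted tree: a tip set is monophyletic iff some
node's leaf descendants equal it exactly; singletons count as (trivially)
monophyletic. Candidate OTU partitions are summarized group by group,
counting the maximal pure sub-clades of any group that fails the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from skbio import TreeNode

from .distances import (
    DistanceMatrix,
    DistanceModelConfig,
    distance_matrix_from_codes,
    encode_sequences,
)
from .otu_stats import Partition

logger = logging.getLogger("barcodedelim")

__all__ = [
    "nj_tree",
    "bootstrap_support",
    "root_with_outgroup",
    "is_monophyletic",
    "monophyly_report",
    "MonophylyStatus",
    "bipartitions",
    "read_newick",
    "write_newick",
]


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree of a distance matrix (unrooted, trifurcating).

    Requires at least 3 labels and all-finite distances; saturated entries
    must be excluded upstream.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if not np.all(np.isfinite(dm.data)):
        raise ValueError(
            "distance matrix contains saturated (non-finite) entries; "
            f"exclude the flagged pairs first: {dm.saturated_pairs[:5]}"
        )
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    # representative label per working node, for deterministic tie-breaks
    reps: list[str] = list(dm.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        # rounding makes Q[i,j] and Q[j,i] differ by ulps; search one triangle
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        i, j = min(ties, key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        parent.extend([a, b])
        newdist = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newdist[keep]
        D2[-1, -1] = 0.0
        D = D2
        rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [rep]

    # closed form for the final three branches: l_a solves the path equations
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, ln in zip((a, b, c), _clamp_triple(la, lb, lc)):
        node.length = ln
    root = TreeNode()
    root.extend([a, b, c])
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sibling."""
    if li < 0.0:
        lj += li
        li = 0.0
        logger.debug("clamped negative NJ branch; deficit moved to sibling")
    if lj < 0.0:
        li += lj
        lj = 0.0
        logger.debug("clamped negative NJ branch; deficit moved to sibling")
    return max(li, 0.0), max(lj, 0.0)


def _clamp_triple(la: float, lb: float, lc: float) -> tuple[float, float, float]:
    vals = [la, lb, lc]
    for i in range(3):
        if vals[i] < 0.0:
            deficit = vals[i]
            vals[i] = 0.0
            j = int(np.argmax(vals))
            vals[j] = max(vals[j] + deficit, 0.0)
    return tuple(vals)  # type: ignore[return-value]


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial leaf bipartitions of a tree, rooted or unrooted.

    Each bipartition is the unordered pair {side, complement}, so the
    representation survives rerooting.
    """
    taxa = frozenset(t.name for t in tree.tips())
    out: set[frozenset[frozenset[str]]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            out.add(frozenset((side, taxa - side)))
    return out


def bootstrap_support(
    aln,
    cfg: DistanceModelConfig | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with bootstrap support percentages on internal nodes.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the reference (full-data) tree is the
    percentage of replicate trees containing the same leaf bipartition.
    Replicates on which a distance is incomputable (no comparable sites or
    saturation) are dropped with a log message; more than 10%% drops is an
    error. Reproducible for a given seed.
    """
    cfg = cfg or DistanceModelConfig()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    codes = encode_sequences([r.seq for r in aln.records])
    ids = aln.ids
    ref_dm = distance_matrix_from_codes(codes, ids, cfg)
    ref_tree = nj_tree(ref_dm)
    ref_bips = bipartitions(ref_tree)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[frozenset[str]], int] = {bp: 0 for bp in ref_bips}
    n_valid = 0
    n_dropped = 0
    L = codes.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        try:
            rep_dm = distance_matrix_from_codes(codes[:, cols], ids, cfg)
            if rep_dm.has_saturated:
                raise ValueError("saturated replicate")
            rep_tree = nj_tree(rep_dm)
        except ValueError:
            n_dropped += 1
            continue
        n_valid += 1
        rep_bips = bipartitions(rep_tree)
        for bp in ref_bips:
            if bp in rep_bips:
                counts[bp] += 1
    if n_dropped:
        logger.info("dropped %d/%d bootstrap replicates", n_dropped, n_reps)
    if n_dropped > 0.1 * n_reps:
        raise ValueError(
            f"{n_dropped}/{n_reps} bootstrap replicates had incomputable distances"
        )
    taxa = frozenset(ids)
    for node in ref_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = frozenset((side, taxa - side))
        if key in counts:
            node.support = 100.0 * counts[key] / n_valid
    return ref_tree


def root_with_outgroup(tree: TreeNode, outgroup_ids: Iterable[str]) -> TreeNode:
    """Root an unrooted tree on the edge separating the outgroup.

    The outgroup must be present and separable by a single edge; otherwise
    the error names the intruding ingroup leaves.
    """
    outgroup = set(outgroup_ids)
    names = {t.name for t in tree.tips()}
    missing = outgroup - names
    if missing:
        raise KeyError(f"outgroup IDs not in tree: {sorted(missing)}")
    if outgroup == names:
        raise ValueError("outgroup cannot contain every leaf")
    if not _separable(tree, outgroup, names):
        lca = tree.lca(list(outgroup))
        intruders = {t.name for t in lca.tips()} - outgroup
        raise ValueError(
            "outgroup is not monophyletic on the unrooted tree; "
            f"intruding leaves include {sorted(intruders)[:5]}"
        )
    return tree.root_by_outgroup(sorted(outgroup))


def _separable(tree: TreeNode, outgroup: set[str], names: set[str]) -> bool:
    """True if some edge bipartitions the leaves into outgroup vs rest."""
    if len(outgroup) in (1, len(names) - 1):
        return True
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if side == outgroup or side == names - outgroup:
            return True
    return False


def is_monophyletic(tree: TreeNode, tips: Iterable[str]) -> bool:
    """True iff *tips* form an exclusive clade on the rooted tree.

    Singleton sets are monophyletic by convention. Unknown tip IDs raise.
    """
    tips = set(tips)
    names = {t.name for t in tree.tips()}
    unknown = tips - names
    if unknown:
        raise KeyError(f"unknown tip IDs: {sorted(unknown)}")
    if len(tips) <= 1:
        return True
    if tips == names:
        return True
    lca = tree.lca(list(tips))
    return {t.name for t in lca.tips()} == tips


@dataclass(frozen=True)
class MonophylyStatus:
    """Per-group monophyly verdict.

    ``status`` is one of ``monophyletic``, ``non-monophyletic``,
    ``singleton`` or ``absent``; ``n_subclades`` counts the maximal pure
    sub-clades of a non-monophyletic group (1 otherwise, None if absent).
    """

    status: str
    n_subclades: int | None

    @property
    def supports(self) -> bool:
        """Whether this status counts as monophyly support for consensus."""
        return self.status in ("monophyletic", "singleton")


def _count_pure_subclades(node: TreeNode, tips: set[str]) -> int:
    """Number of maximal clades under *node* whose leaves are all in *tips*."""
    under = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
    if not under & tips:
        return 0
    if under <= tips:
        return 1
    return sum(_count_pure_subclades(child, tips) for child in node.children)


def monophyly_report(tree: TreeNode, part: Partition) -> dict[str, MonophylyStatus]:
    """Monophyly status of every group of a partition on a rooted tree.

    Groups with no leaves on the tree are reported ``absent``; groups with a
    single leaf are ``singleton``. Non-monophyletic groups carry the count of
    their maximal pure sub-clades.
    """
    names = {t.name for t in tree.tips()}
    out: dict[str, MonophylyStatus] = {}
    for group, members in part.groups().items():
        present = set(members) & names
        if not present:
            out[group] = MonophylyStatus("absent", None)
        elif len(present) == 1:
            out[group] = MonophylyStatus("singleton", 1)
        elif is_monophyletic(tree, present):
            out[group] = MonophylyStatus("monophyletic", 1)
        else:
            k = _count_pure_subclades(tree, present)
            out[group] = MonophylyStatus("non-monophyletic", k)
    return out


def write_newick(tree: TreeNode, path: str | Path, supports: bool = True) -> None:
    """Write Newick; bootstrap supports become internal node labels."""
    if supports:
        for node in tree.non_tips(include_self=False):
            sup = getattr(node, "support", None)
            if sup is not None and node.name is None:
                node.name = f"{sup:g}"
    tree.write(str(path))


def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree (e.g. one produced by external phylogenetics runs)."""
    return TreeNode.read(str(path))
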