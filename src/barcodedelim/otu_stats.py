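"""OTU bookkeeping: threshold clustering, reference assignment, summaries.

This module emulates the registry-style handling of barcode OTUs ("BINs"):

* single-linkage clustering of a distance matrix under a divergence
  threshold (a stand-in for the registry's clustering, whose algorithm is
  proprietary to the registry);
* assignment of unknown sequences to reference OTUs under a similarity
  threshold (default 98.88% — the complement of a 1.12% minimum
  nearest-neighbor distance);
* per-OTU distance summaries (member count, max/mean intra-OTU distance,
  nearest-neighbor OTU and distance, all in percent);
* the barcode-gap diagnostic table (max intra vs. distance-to-NN minus
  max intra; negative values flag OTUs the barcode gap cannot resolve);
* classical metric MDS of a group-level distance matrix for ordination plots.

The clustering, assignment and ordination operations are exposed both as
scikit-learn style estimators (:class:`ThresholdClustering`,
:class:`ReferenceAssigner`, :class:`ClassicalMDS`) and as the plain functions
``threshold_cluster``, ``assign_to_reference`` and ``mds_embed``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin, TransformerMixin

from .distances import (
    DistanceMatrix,
    DistanceModelConfig,
    NoComparableSitesError,
    k2p_distance,
    p_distance,
    site_pattern_counts,
)

logger = logging.getLogger("barcodedelim")

UNASSIGNED = "unassigned"

__all__ = [
    "Partition",
    "OtuSummary",
    "AssignConfig",
    "ThresholdClustering",
    "ReferenceAssigner",
    "ClassicalMDS",
    "threshold_cluster",
    "assign_to_reference",
    "otu_summaries",
    "summaries_table",
    "barcode_gap_table",
    "mds_embed",
    "single_linkage_components",
    "UNASSIGNED",
]


@dataclass
class Partition:
    """A total assignment of sequence IDs to group IDs.

    ``source`` records where the partition came from: threshold clustering,
    barcode-gap discovery, a reference registry, or simulation truth.
    """

    assignment: dict[str, str]
    source: Literal["cluster", "abgd", "reference", "truth"] = "cluster"

    def __post_init__(self) -> None:
        bad = [k for k, v in self.assignment.items() if not v]
        if bad:
            raise ValueError(f"empty group IDs for labels {bad[:5]}")

    @property
    def labels(self) -> list[str]:
        return list(self.assignment)

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[str, list[str]]:
        """Group ID -> member IDs, in first-appearance order."""
        out: dict[str, list[str]] = {}
        for label, g in self.assignment.items():
            out.setdefault(g, []).append(label)
        return out

    def group_of(self, label: str) -> str:
        return self.assignment[label]

    def restrict(self, labels: Sequence[str]) -> "Partition":
        return Partition({l: self.assignment[l] for l in labels}, self.source)

    def as_sets(self) -> frozenset[frozenset[str]]:
        """The partition as a set of member-sets (group names forgotten)."""
        return frozenset(frozenset(m) for m in self.groups().values())

    def same_structure(self, other: "Partition") -> bool:
        """True if both partitions induce the same grouping (names ignored)."""
        return set(self.assignment) == set(other.assignment) and (
            self.as_sets() == other.as_sets()
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"id": list(self.assignment), "group": list(self.assignment.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "cluster") -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["id"], df["group"])), source)


def single_linkage_components(dm: DistanceMatrix, cutoff: float) -> list[list[str]]:
    """Connected components of the graph joining pairs with distance < cutoff.

    Components are ordered by their first member's position in the matrix,
    members in matrix order — deterministic for a given input.
    """
    with np.errstate(invalid="ignore"):
        adj = dm.data < cutoff
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    order: dict[int, int] = {}
    for c in comp:  # renumber components by first appearance
        if c not in order:
            order[c] = len(order)
    members: list[list[str]] = [[] for _ in range(n_comp)]
    for label, c in zip(dm.labels, comp):
        members[order[c]].append(label)
    return members


class ThresholdClustering(ClusterMixin, BaseEstimator):
    """Single-linkage clustering under a fixed distance threshold.

    Two sequences share a cluster iff they are connected by a chain of
    pairwise distances strictly below ``threshold`` (substitutions/site).

    Parameters
    ----------
    threshold : float, default=0.0112
        Distance cutoff; the default is the complement of a 98.88%%
        assignment similarity.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster index per input row (0-based, ordered by first appearance).
    n_clusters_ : int
    """

    def __init__(self, threshold: float = 0.0112):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        dm = _as_distance_matrix(X)
        comps = single_linkage_components(dm, self.threshold)
        idx = {label: k for k, comp in enumerate(comps) for label in comp}
        self.labels_ = np.array([idx[l] for l in dm.labels])
        self.n_clusters_ = len(comps)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _as_distance_matrix(X) -> DistanceMatrix:
    if isinstance(X, DistanceMatrix):
        return X
    X = np.asarray(X, dtype=float)
    return DistanceMatrix([str(i) for i in range(len(X))], X)


def threshold_cluster(dm: DistanceMatrix, threshold: float) -> Partition:
    """Single-linkage partition of *dm* at the given distance threshold."""
    est = ThresholdClustering(threshold=threshold).fit(dm)
    assignment = {
        label: str(k + 1) for label, k in zip(dm.labels, est.labels_)
    }
    return Partition(assignment, source="cluster")


@dataclass(frozen=True)
class AssignConfig:
    """Similarity threshold (percent) and metric for reference assignment."""

    similarity_threshold: float = 98.88
    metric: DistanceModelConfig = field(
        default_factory=lambda: DistanceModelConfig(model="p")
    )

    def __post_init__(self) -> None:
        if not 0 < self.similarity_threshold <= 100:
            raise ValueError("similarity_threshold must be in (0, 100]")


class ReferenceAssigner(ClassifierMixin, BaseEstimator):
    """Assign query sequences to reference OTUs by best-match similarity.

    A query takes the group of its most similar reference sequence when the
    percent similarity, ``100 * (1 - distance)``, reaches
    ``similarity_threshold``; otherwise it is left ``"unassigned"``. Ties on
    the best similarity are broken by reference order with a logged warning.

    Parameters
    ----------
    similarity_threshold : float, default=98.88
        Percent similarity required for assignment.
    metric : {"p", "k2p"}, default="p"
        Distance underlying the similarity (p-distance is the registry
        convention for nearest-neighbor reporting).

    Attributes
    ----------
    classes_ : ndarray of str
        Reference group labels seen during fit.
    """

    def __init__(self, similarity_threshold: float = 98.88, metric: str = "p"):
        self.similarity_threshold = similarity_threshold
        self.metric = metric

    def fit(self, X, y):
        """Fit on reference sequences *X* (strings) with group labels *y*."""
        if not 0 < self.similarity_threshold <= 100:
            raise ValueError("similarity_threshold must be in (0, 100]")
        if self.metric not in ("p", "k2p"):
            raise ValueError("metric must be 'p' or 'k2p'")
        X = list(X)
        y = [str(g) for g in y]
        if not X:
            raise ValueError("reference set is empty")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.ref_seqs_ = X
        self.ref_groups_ = y
        self.classes_ = np.unique(y)
        return self

    def _similarity(self, query: str, ref: str) -> float:
        c = site_pattern_counts(query, ref)
        d = p_distance(c) if self.metric == "p" else k2p_distance(c)
        return 100.0 * (1.0 - d)

    def predict_one(self, query: str) -> tuple[str, float]:
        """Best group (or ``"unassigned"``) and best similarity for one query."""
        sims = []
        n_fail = 0
        for ref in self.ref_seqs_:
            try:
                sims.append(self._similarity(query, ref))
            except NoComparableSitesError:
                sims.append(-np.inf)
                n_fail += 1
        if n_fail == len(sims):
            raise NoComparableSitesError(
                "query shares no comparable sites with any reference"
            )
        best = max(sims)
        hits = [i for i, s in enumerate(sims) if s == best]
        if len(hits) > 1 and len({self.ref_groups_[i] for i in hits}) > 1:
            logger.warning(
                "similarity tie (%.4f) among groups %s; keeping first reference",
                best,
                sorted({self.ref_groups_[i] for i in hits}),
            )
        group = self.ref_groups_[hits[0]]
        return (group if best >= self.similarity_threshold else UNASSIGNED), best

    def predict(self, X):
        return np.array([self.predict_one(q)[0] for q in X], dtype=object)


def assign_to_reference(query, refs, cfg: AssignConfig | None = None) -> str:
    """Assign one query sequence to a reference group, or ``"unassigned"``.

    *refs* is an alignment whose records all carry a ``group``; *query* may
    be a :class:`~barcodedelim.seqio.SequenceRecord` or a plain string.
    """
    cfg = cfg or AssignConfig()
    seqs, groups = [], []
    for rec in refs.records:
        if rec.group is None:
            raise ValueError(f"reference {rec.id!r} has no group label")
        seqs.append(rec.seq)
        groups.append(rec.group)
    est = ReferenceAssigner(
        similarity_threshold=cfg.similarity_threshold, metric=cfg.metric.model
    ).fit(seqs, groups)
    qseq = query if isinstance(query, str) else query.seq
    return est.predict_one(qseq)[0]


@dataclass(frozen=True)
class OtuSummary:
    """Per-OTU distance summary in percent (registry table convention).

    ``max_intra``/``mean_intra`` are ``None`` for singleton OTUs;
    ``nn_group``/``nn_distance`` are ``None`` when fewer than two OTUs exist.
    """

    group: str
    n: int
    max_intra: float | None
    mean_intra: float | None
    nn_group: str | None
    nn_distance: float | None


def otu_summaries(
    dm: DistanceMatrix,
    part: Partition,
    nn_linkage: Literal["min", "mean"] = "min",
) -> list[OtuSummary]:
    """Distance summaries per OTU: n, max/mean intra, nearest neighbor.

    The nearest neighbor of a group is the other group minimizing the
    cross-group linkage — the minimum cross pairwise distance by default
    (registry convention), or the mean with ``nn_linkage="mean"``.
    Distances are reported in percent.
    """
    unassigned = [l for l in dm.labels if l not in part.assignment]
    if unassigned:
        raise KeyError(f"labels without group assignment: {unassigned}")
    groups = part.restrict(dm.labels).groups()
    names = list(groups)
    idx = {g: [dm.index(l) for l in members] for g, members in groups.items()}
    if len(names) < 2:
        warnings.warn("fewer than 2 groups: nearest-neighbor fields undefined",
                      stacklevel=2)
    out: list[OtuSummary] = []
    for g in names:
        ia = idx[g]
        if len(ia) > 1:
            sub = dm.data[np.ix_(ia, ia)][np.triu_indices(len(ia), k=1)]
            max_intra: float | None = 100.0 * float(np.max(sub))
            mean_intra: float | None = 100.0 * float(np.mean(sub))
        else:
            max_intra = mean_intra = None
        nn_group = nn_distance = None
        if len(names) >= 2:
            best = np.inf
            for h in names:
                if h == g:
                    continue
                cross = dm.data[np.ix_(ia, idx[h])]
                link = float(np.min(cross) if nn_linkage == "min" else np.mean(cross))
                if link < best:
                    best, nn_group = link, h
            nn_distance = 100.0 * best
        out.append(OtuSummary(g, len(ia), max_intra, mean_intra, nn_group, nn_distance))
    return out


def summaries_table(summaries: Sequence[OtuSummary]) -> pd.DataFrame:
    """Summaries as a registry-style table (group, N, Max, Mean, NN, dist)."""
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "N": s.n,
                "max_intra": s.max_intra,
                "mean_intra": s.mean_intra,
                "NN": s.nn_group,
                "dist_to_NN": s.nn_distance,
            }
            for s in summaries
        ]
    )


def barcode_gap_table(summaries: Sequence[OtuSummary]) -> pd.DataFrame:
    """Barcode-gap scatter points: x = max intra, y = dist-to-NN - max intra.

    OTUs without defined intra statistics (singletons) or without a nearest
    neighbor are excluded — they cannot be tested. ``y <= 0`` flags an OTU
    the barcode gap does not resolve.
    """
    rows = []
    for s in summaries:
        if s.max_intra is None or s.nn_distance is None:
            continue
        y = s.nn_distance - s.max_intra
        rows.append(
            {
                "group": s.group,
                "x_max_intra": s.max_intra,
                "nn_distance": s.nn_distance,
                "y_gap": y,
                "resolved": y > 0,
            }
        )
    return pd.DataFrame(rows, columns=["group", "x_max_intra", "nn_distance",
                                       "y_gap", "resolved"])


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Classical (metric) multidimensional scaling of a distance matrix.

    Eigendecomposition of the double-centered matrix of squared distances;
    coordinates are ordered by eigenvalue and deterministic up to sign (the
    sign is fixed so each axis's largest-magnitude coordinate is positive).

    Parameters
    ----------
    n_components : int, default=2

    Attributes
    ----------
    embedding_ : ndarray of shape (n, n_components)
    eigenvalues_ : ndarray
        All eigenvalues, descending.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        D = _as_distance_matrix(X).data
        n = D.shape[0]
        k = self.n_components
        if n < 3:
            raise ValueError("classical MDS needs at least 3 points")
        if not k < n:
            raise ValueError("n_components must be smaller than the number of points")
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ (D**2) @ J
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if np.all(evals[:k] <= 0):
            raise ValueError(
                "distance matrix is heavily non-Euclidean: no positive eigenvalue "
                "among the leading components"
            )
        coords = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0.0, None))
        for j in range(k):  # deterministic sign convention
            i = np.argmax(np.abs(coords[:, j]))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
        self.eigenvalues_ = evals
        self.embedding_ = coords
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def mds_embed(group_dm: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    """Classical MDS coordinates of a group-level distance matrix."""
    est = ClassicalMDS(n_components=k).fit(group_dm)
    return pd.DataFrame(
        est.embedding_,
        index=group_dm.labels,
        columns=[f"axis{i + 1}" for i in range(k)],
    )
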