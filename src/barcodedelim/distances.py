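"""Pairwise genetic distances: p, Kimura 2-parameter, Tamura-Nei (TN93).

All distances are computed from per-pair site-pattern counts under pairwise
deletion: for each sequence pair, only the alignment columns where both
sequences carry an unambiguous base (A/C/G/T) are compared, matching the
convention of BOLD and MEGA. Differences are partitioned into the two
transition classes (A<->G, C<->T) and transversions, which is exactly the
sufficient statistic for the three substitution models implemented here:

* p-distance: raw proportion of differing sites.
* K2P: ``d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`` with transition proportion P
  and transversion proportion Q.
* TN93: separates the A<->G (P1) and C<->T (P2) transition proportions and
  weights them by the base frequencies; optionally gamma rate-corrected with
  shape alpha, where each ``-ln(w)`` term becomes ``alpha * (w**(-1/alpha) - 1)``.

Distances are expressed in substitutions per site throughout; conversion to
percent happens only at the presentation layer (OTU summary tables).

Saturated pairs (a logarithm argument <= 0, possible for extremely divergent
sequences) are recorded as ``+inf`` and flagged on the resulting matrix rather
than raised, so that downstream ranking can place them last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SitePatternCounts",
    "DistanceModelConfig",
    "DistanceMatrix",
    "NoComparableSitesError",
    "DegenerateFrequenciesError",
    "site_pattern_counts",
    "p_distance",
    "k2p_distance",
    "tn93_distance",
    "distance_matrix",
    "group_distance_summary",
    "encode_sequences",
]

# base encoding: A=0, C=1, G=2, T=3, anything else (N, gap) = 4.
# purines (A, G) are even, pyrimidines (C, T) odd, so transition vs
# transversion is a parity test.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

BASES = ("A", "C", "G", "T")


class NoComparableSitesError(ValueError):
    """A sequence pair shares no columns with unambiguous bases in both."""


class DegenerateFrequenciesError(ValueError):
    """A base class required by TN93 has zero frequency in the compared sites."""


def encode_sequences(seqs: Iterable[str]) -> np.ndarray:
    """Encode sequences into a (n, L) uint8 matrix (A=0,C=1,G=2,T=3, other=4)."""
    rows = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths {sorted(lengths)}")
    return _CODE[np.vstack(rows)]


@dataclass(frozen=True)
class SitePatternCounts:
    """Sufficient statistics of one pairwise comparison (pairwise deletion).

    Attributes
    ----------
    n_sites : int
        Number of compared sites (both bases in A/C/G/T).
    n_ts_AG, n_ts_CT : int
        A<->G and C<->T transition counts.
    n_tv : int
        Transversion count.
    base_counts : tuple of int
        Counts of A, C, G, T pooled over both sequences at compared sites
        (sums to ``2 * n_sites``).
    """

    n_sites: int
    n_ts_AG: int
    n_ts_CT: int
    n_tv: int
    base_counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_ts_AG, self.n_ts_CT, self.n_tv) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_ts_AG + self.n_ts_CT + self.n_tv > self.n_sites:
            raise ValueError("difference counts exceed number of compared sites")
        if sum(self.base_counts) != 2 * self.n_sites:
            raise ValueError("base_counts must sum to 2 * n_sites")

    @property
    def P(self) -> float:
        """Total transition proportion."""
        return (self.n_ts_AG + self.n_ts_CT) / self.n_sites

    @property
    def P1(self) -> float:
        """A<->G transition proportion."""
        return self.n_ts_AG / self.n_sites

    @property
    def P2(self) -> float:
        """C<->T transition proportion."""
        return self.n_ts_CT / self.n_sites

    @property
    def Q(self) -> float:
        """Transversion proportion."""
        return self.n_tv / self.n_sites

    @property
    def base_freqs(self) -> np.ndarray:
        """Pooled base frequencies (piA, piC, piG, piT) at compared sites."""
        return np.asarray(self.base_counts, dtype=float) / (2 * self.n_sites)


@dataclass(frozen=True)
class DistanceModelConfig:
    """Substitution model choice for distance computation.

    ``gamma_shape`` (alpha) enables gamma rate correction and is meaningful
    for the TN93 model only. ``global_freqs=True`` estimates the TN93 base
    frequencies once from the whole alignment instead of per pair.
    """

    model: Literal["p", "k2p", "tn93"] = "tn93"
    gamma_shape: float | None = None
    global_freqs: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("p", "k2p", "tn93"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.gamma_shape is not None:
            if self.model != "tn93":
                raise ValueError("gamma_shape is only supported for the tn93 model")
            if not self.gamma_shape > 0:
                raise ValueError("gamma_shape must be positive")


def site_pattern_counts(a: str | np.ndarray, b: str | np.ndarray) -> SitePatternCounts:
    """Count site patterns between two equal-length sequences.

    Columns where either sequence is not a plain A/C/G/T (N, gap, anything
    else) are excluded — pairwise deletion.
    """
    ca = encode_sequences([a])[0] if isinstance(a, str) else np.asarray(a)
    cb = encode_sequences([b])[0] if isinstance(b, str) else np.asarray(b)
    if ca.shape != cb.shape:
        raise ValueError(f"sequences have unequal lengths {ca.size} and {cb.size}")
    mask = (ca < 4) & (cb < 4)
    x, y = ca[mask], cb[mask]
    n = int(x.size)
    if n == 0:
        raise NoComparableSitesError("no comparable sites between the two sequences")
    diff = x != y
    even_x, even_y = (x & 1) == 0, (y & 1) == 0
    n_ts_ag = int(np.count_nonzero(diff & even_x & even_y))
    n_ts_ct = int(np.count_nonzero(diff & ~even_x & ~even_y))
    n_tv = int(np.count_nonzero(diff)) - n_ts_ag - n_ts_ct
    counts = np.bincount(x, minlength=4) + np.bincount(y, minlength=4)
    return SitePatternCounts(n, n_ts_ag, n_ts_ct, n_tv, tuple(int(c) for c in counts[:4]))


def p_distance(c: SitePatternCounts) -> float:
    """Proportion of differing sites among compared sites."""
    return (c.n_ts_AG + c.n_ts_CT + c.n_tv) / c.n_sites


def k2p_distance(c: SitePatternCounts) -> float:
    """Kimura 2-parameter distance; ``+inf`` when saturated."""
    P, Q = c.P, c.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _gamma_log(w: float, alpha: float | None) -> float:
    """The TN93 transform of -ln(w): gamma-corrected when alpha is given."""
    if alpha is None:
        return -math.log(w)
    return alpha * (w ** (-1.0 / alpha) - 1.0)


def tn93_distance(
    c: SitePatternCounts,
    gamma_shape: float | None = None,
    freqs: Sequence[float] | None = None,
) -> float:
    """Tamura-Nei (TN93) distance, optionally gamma rate-corrected.

    Base frequencies default to the pair's pooled compared-site frequencies;
    pass *freqs* to use alignment-wide estimates instead. Returns ``+inf``
    when saturated; raises :class:`DegenerateFrequenciesError` when a base
    class required by the model is absent.
    """
    pi = np.asarray(freqs, dtype=float) if freqs is not None else c.base_freqs
    for i, name in enumerate(BASES):
        if pi[i] <= 0.0:
            raise DegenerateFrequenciesError(
                f"base {name} absent from compared sites; TN93 undefined"
            )
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    k1 = 2.0 * piA * piG / piR
    k2 = 2.0 * piT * piC / piY
    k3 = 2.0 * (piR * piY - piA * piG * piY / piR - piT * piC * piR / piY)
    P1, P2, Q = c.P1, c.P2, c.Q
    w1 = 1.0 - P1 / k1 - Q / (2.0 * piR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * piY)
    w3 = 1.0 - Q / (2.0 * piR * piY)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return math.inf
    return (
        k1 * _gamma_log(w1, gamma_shape)
        + k2 * _gamma_log(w2, gamma_shape)
        + k3 * _gamma_log(w3, gamma_shape)
    )


def pair_distance(c: SitePatternCounts, cfg: DistanceModelConfig,
                  freqs: Sequence[float] | None = None) -> float:
    """Distance for one pair under the configured model."""
    if cfg.model == "p":
        return p_distance(c)
    if cfg.model == "k2p":
        return k2p_distance(c)
    return tn93_distance(c, gamma_shape=cfg.gamma_shape, freqs=freqs)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labels and model provenance."""

    labels: list[str]
    data: np.ndarray
    model: DistanceModelConfig = field(default_factory=DistanceModelConfig)
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError(f"data shape {self.data.shape} does not match {n} labels")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.data)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            self.data[finite & finite.T], self.data.T[finite & finite.T]
        ):
            raise ValueError("matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def has_saturated(self) -> bool:
        return bool(self.saturated_pairs)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.index(pair[0]), self.index(pair[1])
        return float(self.data[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major order (n*(n-1)/2 entries)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.data[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        sat = [
            (a, b) for a, b in self.saturated_pairs if a in set(labels) and b in set(labels)
        ]
        return DistanceMatrix(list(labels), self.data[np.ix_(idx, idx)], self.model, sat)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        """Square TSV with labels in the first row and column."""
        self.to_dataframe().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 model: DistanceModelConfig | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        labels = list(df.index)
        data = df.to_numpy(dtype=float)
        iu = np.triu_indices(len(labels), k=1)
        sat = [
            (labels[i], labels[j])
            for i, j in zip(*iu)
            if not np.isfinite(data[i, j])
        ]
        return cls(labels, data, model or DistanceModelConfig(), sat)

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square (lower+upper) format."""
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.data):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{label[:10].ljust(10)}  {vals}\n")

    def to_skbio(self):
        """As a ``skbio.DistanceMatrix`` (requires all-finite entries)."""
        import skbio

        return skbio.DistanceMatrix(self.data, ids=self.labels)


def distance_matrix(aln, cfg: DistanceModelConfig | None = None) -> DistanceMatrix:
    """Full pairwise distance matrix of an alignment under *cfg*.

    Raises :class:`NoComparableSitesError` naming the first offending pair;
    saturated pairs are recorded as ``+inf`` and listed on the result.
    """
    cfg = cfg or DistanceModelConfig()
    ids = aln.ids
    if len(ids) < 2:
        raise ValueError("distance computation needs at least 2 records")
    codes = encode_sequences([r.seq for r in aln.records])
    return distance_matrix_from_codes(codes, ids, cfg)


def distance_matrix_from_codes(
    codes: np.ndarray, ids: Sequence[str], cfg: DistanceModelConfig
) -> DistanceMatrix:
    """Distance matrix from an encoded (n, L) base matrix (see encode_sequences)."""
    n = len(ids)
    data = np.zeros((n, n), dtype=float)
    saturated: list[tuple[str, str]] = []
    freqs = None
    if cfg.model == "tn93" and cfg.global_freqs:
        pooled = np.bincount(codes[codes < 4].ravel(), minlength=4)[:4]
        freqs = pooled / pooled.sum()
    for i in range(n - 1):
        for j in range(i + 1, n):
            try:
                c = site_pattern_counts(codes[i], codes[j])
            except NoComparableSitesError as exc:
                raise NoComparableSitesError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                ) from exc
            d = pair_distance(c, cfg, freqs=freqs)
            if math.isinf(d):
                saturated.append((ids[i], ids[j]))
            data[i, j] = data[j, i] = d
    return DistanceMatrix(list(ids), data, cfg, saturated)


def group_distance_summary(dm: DistanceMatrix, part, between: bool = True):
    """Group-level mean distances.

    With ``between=True`` (default) returns a square DataFrame whose
    off-diagonal entries are the means of all cross-group pairwise distances
    and whose diagonal holds the within-group means (NaN for singletons).
    With ``between=False`` returns only the within-group means as a Series.

    Raises ``KeyError`` if any matrix label lacks a group assignment.
    """
    assignment = part.assignment if hasattr(part, "assignment") else dict(part)
    unassigned = [l for l in dm.labels if l not in assignment]
    if unassigned:
        raise KeyError(f"labels without group assignment: {unassigned}")
    groups: dict[str, list[int]] = {}
    for idx, label in enumerate(dm.labels):
        groups.setdefault(assignment[label], []).append(idx)
    names = list(groups)
    k = len(names)
    out = np.full((k, k), np.nan)
    for a in range(k):
        ia = groups[names[a]]
        if len(ia) > 1:
            sub = dm.data[np.ix_(ia, ia)]
            out[a, a] = sub[np.triu_indices(len(ia), k=1)].mean()
        for b in range(a + 1, k):
            ib = groups[names[b]]
            cross = dm.data[np.ix_(ia, ib)]
            out[a, b] = out[b, a] = cross.mean()
    df = pd.DataFrame(out, index=names, columns=names)
    if not between:
        return pd.Series(np.diag(df.to_numpy()), index=names, name="within_mean")
    return df
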