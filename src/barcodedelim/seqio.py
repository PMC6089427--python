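"""Sequence, alignment and metadata I/O for aligned barcode data.

The in-memory model is a light :class:`Alignment` of :class:`SequenceRecord`
objects: aligned DNA barcode sequences (typically ~650 bp of COI) carrying the
per-specimen metadata the downstream delimitation stages use (taxon label,
known OTU/BIN group, basin, coordinates).

Sequences are stored uppercase over the alphabet ``{A, C, G, T, N, -}``.
IUPAC ambiguity codes other than N (R, Y, S, W, ...) are mapped to N on input,
with the number of replacements logged: the distance models downstream treat
only unambiguous A/C/G/T sites as informative, so partial ambiguity carries no
extra information for them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("barcodedelim")

__all__ = [
    "SequenceRecord",
    "Alignment",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "write_nexus",
    "read_metadata",
    "write_metadata",
]

#: characters a stored sequence may contain
VALID_CHARS = frozenset("ACGTN-")

#: IUPAC ambiguity codes collapsed to N on input
AMBIGUITY_CODES = frozenset("RYSWKMBDHVU?")

#: metadata table columns understood by :func:`read_metadata`
METADATA_COLUMNS = ("id", "taxon", "group", "basin", "lat", "lon")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged lengths, duplicate IDs, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence plus its specimen metadata.

    Parameters
    ----------
    id : str
        Unique sequence identifier (accession-style IDs are treated as opaque).
    seq : str
        Aligned sequence over ``{A,C,G,T,N,-}``; stored uppercase.
    taxon : str
        Free-text taxonomic label; may be empty.
    group : str or None
        Known OTU/BIN label, if any.
    basin : str or None
        Drainage basin or other locality grouping.
    lat, lon : float or None
        Decimal-degree coordinates.
    """

    id: str
    seq: str
    taxon: str = ""
    group: str | None = None
    basin: str | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        bad = set(seq) - VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}; "
                "sanitize input with read_fasta or sanitize_sequence"
            )
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} of {self.id!r} outside [-90, 90]")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} of {self.id!r} outside [-180, 180]")

    def __len__(self) -> int:
        return len(self.seq)


def sanitize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase *seq* and collapse non-N ambiguity codes to N.

    Returns the cleaned sequence and the number of characters replaced.
    """
    seq = seq.upper()
    n_mapped = sum(1 for c in seq if c in AMBIGUITY_CODES)
    if n_mapped:
        seq = "".join("N" if c in AMBIGUITY_CODES else c for c in seq)
    return seq, n_mapped


@dataclass
class Alignment:
    """An ordered collection of equal-length :class:`SequenceRecord` objects."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise AlignmentError(f"duplicate sequence IDs: {sorted(dupes)}")
        ref = len(self.records[0])
        offenders = [r.id for r in self.records if len(r) != ref]
        if offenders:
            raise AlignmentError(
                f"unequal sequence lengths (expected {ref} sites): "
                f"offending IDs {offenders}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def select(self, ids: Iterable[str]) -> "Alignment":
        """Sub-alignment restricted to *ids*, in this alignment's order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"IDs not in alignment: {sorted(missing)}")
        return Alignment([r for r in self.records if r.id in wanted])

    def groups(self) -> dict[str, list[str]]:
        """Map of known group label -> member IDs (records without a group skipped)."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            if r.group is not None:
                out.setdefault(r.group, []).append(r.id)
        return out


def read_fasta(path: str | Path, metadata_path: str | Path | None = None) -> Alignment:
    """Read an aligned FASTA file, optionally joining a metadata table by ID.

    Ambiguity codes other than N are collapsed to N (count logged). Raises
    :class:`AlignmentError` on ragged lengths, duplicate IDs or an empty file.
    Metadata rows without a matching sequence are reported as warnings.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    total_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, n_mapped = sanitize_sequence(str(rec.seq))
        total_mapped += n_mapped
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    if total_mapped:
        logger.info("mapped %d ambiguity characters to N while reading %s",
                    total_mapped, path)
    aln = Alignment(records)
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        aln = join_metadata(aln, meta)
    return aln


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated metadata table keyed by sequence ID.

    Expected header ``id taxon group basin lat lon``; unknown columns are
    preserved in the returned frame but ignored by :func:`join_metadata`.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in meta.columns:
        raise ValueError(f"metadata table {path} lacks an 'id' column")
    return meta


def join_metadata(aln: Alignment, meta: pd.DataFrame) -> Alignment:
    """Attach metadata rows to alignment records by ID (order-independent)."""
    by_id = meta.set_index("id", drop=False)
    if by_id.index.has_duplicates:
        dupes = sorted(by_id.index[by_id.index.duplicated()].unique())
        raise ValueError(f"duplicate metadata IDs: {dupes}")
    unmatched = sorted(set(by_id.index) - set(aln.ids))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} metadata rows without a matching sequence: "
            f"{unmatched[:10]}{'...' if len(unmatched) > 10 else ''}",
            stacklevel=2,
        )

    def _get(row: pd.Series, col: str):
        if col not in row or pd.isna(row[col]):
            return None
        return row[col]

    out = []
    for rec in aln.records:
        if rec.id in by_id.index:
            row = by_id.loc[rec.id]
            out.append(
                replace(
                    rec,
                    taxon=str(_get(row, "taxon") or ""),
                    group=(None if _get(row, "group") is None else str(row["group"])),
                    basin=(None if _get(row, "basin") is None else str(row["basin"])),
                    lat=(None if _get(row, "lat") is None else float(row["lat"])),
                    lon=(None if _get(row, "lon") is None else float(row["lon"])),
                )
            )
        else:
            out.append(rec)
    return Alignment(out)


def write_fasta(aln: Alignment, path: str | Path, width: int = 80) -> None:
    """Write *aln* as FASTA with *width*-column sequence wrapping."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_metadata(aln: Alignment, path: str | Path) -> None:
    """Write the alignment's metadata as the standard six-column TSV."""
    rows = [
        {
            "id": r.id,
            "taxon": r.taxon,
            "group": r.group,
            "basin": r.basin,
            "lat": r.lat,
            "lon": r.lon,
        }
        for r in aln.records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_nexus(aln: Alignment, path: str | Path) -> None:
    """Write a NEXUS DATA block (for hand-off to external tree software).

    Declares ``ntax``, ``nchar``, ``datatype=DNA``, ``gap=-`` and ``missing=N``.
    """
    path = Path(path)
    name_w = max(len(r.id) for r in aln.records)
    with path.open("w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(aln)} NCHAR={aln.n_sites};\n")
        fh.write("    FORMAT DATATYPE=DNA GAP=- MISSING=N;\n")
        fh.write("    MATRIX\n")
        for rec in aln.records:
            fh.write(f"    {rec.id.ljust(name_w)}  {rec.seq}\n")
        fh.write("    ;\nEND;\n")
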