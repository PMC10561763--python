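"""FASTA and bedgraph depth-track I/O, and fixed-width genome windowing.

Coordinates are 0-based half-open everywhere (bedgraph convention). FASTA
headers are truncated at the first whitespace to form contig ids. Sequences
are restricted to the {A, C, G, T, N} alphabet after uppercasing; other
IUPAC ambiguity codes are rejected so that window GC is always well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "Contig",
    "DepthTrack",
    "read_fasta",
    "write_fasta",
    "make_windows",
    "read_depth_bedgraph",
    "write_depth_bedgraph",
]


@dataclass(frozen=True)
class Contig:
    """A named assembly sequence over the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid contig id {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _validate_sequence(cid: str, seq: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        pos = next(i for i, ch in enumerate(seq) if ch in bad)
        raise ValueError(
            f"contig {cid!r}: non-ACGTN character {seq[pos]!r} at position {pos}"
        )


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA assembly into a list of :class:`Contig`.

    Record order is preserved; sequences are uppercased; ids are the header
    up to the first whitespace and must be unique.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        cid = rec.id
        if cid in seen:
            raise ValueError(f"duplicate contig id {cid!r}")
        seen.add(cid)
        seq = str(rec.seq).upper()
        _validate_sequence(cid, seq)
        contigs.append(Contig(cid, seq))
    if not contigs:
        raise ValueError(f"no records in FASTA file {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def make_windows(
    contig_length: int, window_size: int, step: int | None = None
) -> list[tuple[int, int]]:
    """Tile ``[0, contig_length)`` with half-open windows.

    With the default ``step == window_size`` the windows partition the contig
    exactly (the last window is truncated at the contig end). A smaller step
    yields overlapping windows and is exposed for plotting only; the pipeline
    always uses the tiling default so depth is never double-counted.
    """
    if contig_length < 1 or window_size < 1:
        raise ValueError("contig_length and window_size must be >= 1")
    if step is None:
        step = window_size
    if step < 1 or step > window_size:
        raise ValueError("step must satisfy 1 <= step <= window_size")
    out = []
    start = 0
    while start < contig_length:
        out.append((start, min(start + window_size, contig_length)))
        if start + window_size >= contig_length:
            break
        start += step
    return out


@dataclass
class DepthTrack:
    """Sparse per-base depth for one sample, queryable by interval.

    Positions not covered by any bedgraph record have depth 0.
    """

    lengths: dict[str, int]
    _starts: dict[str, np.ndarray] = field(default_factory=dict)
    _ends: dict[str, np.ndarray] = field(default_factory=dict)
    _depths: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, int, float]],
        lengths: dict[str, int],
    ) -> "DepthTrack":
        by_contig: dict[str, list[tuple[int, int, float]]] = {}
        for cid, start, end, depth in records:
            if cid not in lengths:
                raise ValueError(f"depth record references unknown contig {cid!r}")
            if not (0 <= start < end <= lengths[cid]):
                raise ValueError(
                    f"depth record {cid}:{start}-{end} out of bounds "
                    f"(contig length {lengths[cid]})"
                )
            if depth < 0:
                raise ValueError(f"negative depth at {cid}:{start}-{end}")
            by_contig.setdefault(cid, []).append((start, end, depth))
        track = cls(lengths=dict(lengths))
        for cid, rows in by_contig.items():
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            depths = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < starts[:-1]):
                raise ValueError(f"bedgraph records for {cid} are not sorted")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bedgraph records on {cid}")
            track._starts[cid] = starts
            track._ends[cid] = ends
            track._depths[cid] = depths
        return track

    def mean_depth(self, contig_id: str, start: int, end: int) -> float:
        """Mean per-base depth over ``[start, end)``; uncovered bases count 0."""
        if contig_id not in self.lengths:
            raise ValueError(f"unknown contig {contig_id!r}")
        if not (0 <= start < end <= self.lengths[contig_id]):
            raise ValueError(f"query {contig_id}:{start}-{end} out of bounds")
        if contig_id not in self._starts:
            return 0.0
        starts = self._starts[contig_id]
        ends = self._ends[contig_id]
        depths = self._depths[contig_id]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        overlap = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(overlap * depths[lo:hi]) / (end - start))


def read_depth_bedgraph(
    path: str | Path, assembly: Sequence[Contig]
) -> DepthTrack:
    """Parse a 4-column bedgraph (contig, start, end, depth) into a DepthTrack."""
    lengths = {c.id: c.length for c in assembly}

    def _records() -> Iterator[tuple[str, int, int, float]]:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                    )
                yield parts[0], int(parts[1]), int(parts[2]), float(parts[3])

    return DepthTrack.from_records(_records(), lengths)


def write_depth_bedgraph(
    windows: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    """Write (contig, start, end, depth) records as tab-delimited bedgraph.

    Depths are serialized with 4 decimal places.
    """
    with open(path, "w") as fh:
        for cid, start, end, depth in windows:
            fh.write(f"{cid}\t{start}\t{end}\t{depth:.4f}\n")
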