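"""Assembly summary statistics: Nx/Lx, GC%, class fractions, fold ratios."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import Contig

__all__ = ["AssemblyStats", "nx_stat", "fold_ratio", "summarize_assembly"]


def nx_stat(lengths: Sequence[int], x: float = 50) -> tuple[int, int]:
    """(Nx, Lx) of a length multiset.

    Nx is the length of the shortest sequence in the smallest set of longest
    sequences whose summed length reaches >= x% of the total; Lx is the
    number of sequences in that set. The cumulative comparison uses >=, the
    dominant convention.
    """
    if len(lengths) == 0:
        raise ValueError("empty length list")
    if not (0 < x <= 100):
        raise ValueError(f"x must be in (0, 100], got {x}")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if np.any(arr < 1):
        raise ValueError("lengths must be >= 1")
    cum = np.cumsum(arr)
    threshold = x / 100.0 * cum[-1]
    idx = int(np.searchsorted(cum, threshold, side="left"))
    return int(arr[idx]), idx + 1


def fold_ratio(size_a: float, size_b: float, decimals: int = 1) -> float:
    """``size_a / size_b`` rounded to ``decimals`` places (round-half-to-even)."""
    if size_b == 0:
        raise ValueError("zero denominator")
    return round(size_a / size_b, decimals)


@dataclass(frozen=True)
class AssemblyStats:
    n_seqs: int
    total_bp: int
    n50: int
    l50: int
    longest: int
    gc_percent: float
    class_bp: dict[str, int] = field(default_factory=dict)

    @property
    def class_fractions(self) -> dict[str, float]:
        """Per-class bp as a percentage of the assembly total."""
        return {k: 100.0 * v / self.total_bp for k, v in self.class_bp.items()}

    def to_text(self) -> str:
        rows = [
            ("Number of sequences", f"{self.n_seqs:,}"),
            ("Total size (bp)", f"{self.total_bp:,}"),
            ("N50 (bp)", f"{self.n50:,}"),
            ("L50", f"{self.l50:,}"),
            ("Longest sequence (bp)", f"{self.longest:,}"),
            ("G+C contents (%)", f"{self.gc_percent:.1f}"),
        ]
        for cls, frac in self.class_fractions.items():
            rows.append((f"{cls} content (%)", f"{frac:.1f}"))
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {value}" for name, value in rows)

    def to_tsv(self) -> str:
        lines = [
            f"n_seqs\t{self.n_seqs}",
            f"total_bp\t{self.total_bp}",
            f"n50\t{self.n50}",
            f"l50\t{self.l50}",
            f"longest\t{self.longest}",
            f"gc_percent\t{self.gc_percent:.4f}",
        ]
        for cls, bp in self.class_bp.items():
            lines.append(f"class_bp:{cls}\t{bp}")
        return "\n".join(lines) + "\n"


def summarize_assembly(
    contigs: Sequence[Contig], class_map: Mapping[str, str] | None = None
) -> AssemblyStats:
    """Table-style summary of an assembly.

    GC% is computed over non-N bases. With a ``class_map`` (contig id →
    class label) per-class bp totals are reported; unannotated contigs are
    simply left out of the class breakdown.
    """
    if len(contigs) == 0:
        raise ValueError("empty assembly")
    lengths = [c.length for c in contigs]
    n50, l50 = nx_stat(lengths, 50)
    gc = sum(c.sequence.count("G") + c.sequence.count("C") for c in contigs)
    acgt = sum(c.length - c.sequence.count("N") for c in contigs)
    class_bp: dict[str, int] = {}
    if class_map:
        for c in contigs:
            cls = class_map.get(c.id)
            if cls is not None:
                class_bp[cls] = class_bp.get(cls, 0) + c.length
    return AssemblyStats(
        n_seqs=len(contigs),
        total_bp=sum(lengths),
        n50=n50,
        l50=l50,
        longest=max(lengths),
        gc_percent=100.0 * gc / acgt if acgt else float("nan"),
        class_bp=class_bp,
    )
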