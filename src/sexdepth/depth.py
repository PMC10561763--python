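"""Per-window GC and mean raw depth: the table every downstream stage consumes.

A :class:`WindowTable` holds, for one sample, the tiling windows of every
contig with their GC fraction and mean raw depth. Windows that are more than
half N (or whose GC is undefined because they are all-N) are flagged
``excluded``: they are left out of GC-model fitting and of the global depth
baseline, but still receive a corrected depth later so that gappy contigs
are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Contig, DepthTrack, make_windows

__all__ = ["WindowTable", "window_gc", "profile_sample"]

MAX_N_FRACTION = 0.5

_COLUMNS = ["contig", "start", "end", "gc", "raw_depth", "excluded"]


def _base_counts(seq_bytes: np.ndarray, start: int, end: int) -> tuple[int, int]:
    """(#G+#C, #A+#C+#G+#T) over seq_bytes[start:end]."""
    window = seq_bytes[start:end]
    gc = int(np.sum((window == ord("G")) | (window == ord("C"))))
    n = int(np.sum(window == ord("N")))
    return gc, (end - start) - n


def window_gc(contig: Contig, start: int, end: int) -> float:
    """GC fraction of ``contig[start:end)``; NaN when the window is all N.

    N bases are excluded from the denominator, so a window of "ATGCNN" has
    GC 0.5.
    """
    if not (0 <= start < end <= contig.length):
        raise ValueError(
            f"window {start}-{end} out of bounds for contig "
            f"{contig.id!r} (length {contig.length})"
        )
    seq_bytes = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
    gc, acgt = _base_counts(seq_bytes, start, end)
    return gc / acgt if acgt > 0 else float("nan")


@dataclass
class WindowTable:
    """Windowed GC/depth table for one sample.

    ``data`` columns: contig, start, end, gc, raw_depth, excluded.
    ``global_raw_mean`` is the length-weighted mean raw depth over
    non-excluded windows — the reproducible stand-in for the sample's
    overall sequencing depth.
    """

    data: pd.DataFrame
    sample_id: str
    sex: str
    window_size: int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        missing = set(_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"window table missing columns {sorted(missing)}")

    @property
    def global_raw_mean(self) -> float:
        rows = self.data[~self.data["excluded"]]
        if rows.empty:
            return float("nan")
        weights = (rows["end"] - rows["start"]).to_numpy(dtype=float)
        return float(np.average(rows["raw_depth"], weights=weights))

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "sample_id", self.sample_id)
        out.insert(1, "sex", self.sex)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, window_size: int) -> "WindowTable":
        df = pd.read_csv(path, sep="\t")
        sample_id = str(df["sample_id"].iloc[0])
        sex = str(df["sex"].iloc[0])
        return cls(
            data=df[_COLUMNS].copy(),
            sample_id=sample_id,
            sex=sex,
            window_size=window_size,
        )


def profile_sample(
    assembly: Sequence[Contig],
    track: DepthTrack,
    window_size: int,
    sample_id: str,
    sex: str,
) -> WindowTable:
    """Tile every contig and attach window GC plus mean raw depth.

    Windows with more than :data:`MAX_N_FRACTION` N bases, or with undefined
    GC, are flagged excluded.
    """
    rows = []
    for contig in assembly:
        seq_bytes = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
        for start, end in make_windows(contig.length, window_size):
            gc_count, acgt = _base_counts(seq_bytes, start, end)
            width = end - start
            gc = gc_count / acgt if acgt > 0 else float("nan")
            n_fraction = (width - acgt) / width
            excluded = n_fraction > MAX_N_FRACTION or acgt == 0
            rows.append(
                (
                    contig.id,
                    start,
                    end,
                    gc,
                    track.mean_depth(contig.id, start, end),
                    excluded,
                )
            )
    data = pd.DataFrame(rows, columns=_COLUMNS)
    return WindowTable(data=data, sample_id=sample_id, sex=sex, window_size=window_size)
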