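"""Copy-number estimation from corrected window depths.

A window's copy number is ``2 * corrected_depth / baseline_depth`` where the
baseline is the sample's own reference depth, so an ordinary diploid window
sits at cn = 2, a male X window at cn = 1 and a female Y window at cn = 0 —
the scale on which "single copy", "twofold" and "not detectable" read
literally. Contigs are summarized by the *median* window cn, which resists
collapsed-repeat and pileup windows. Replicates of one sex are combined by
averaging window copy numbers across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .depth import WindowTable
from .gc_correction import GCModel

__all__ = [
    "CopyNumberProfile",
    "window_cn",
    "contig_cn",
    "profile_copy_number",
    "combine_replicates",
]

DEFAULT_MIN_WINDOWS = 3

_WINDOW_COLUMNS = ["contig", "start", "end", "excluded", "cn"]
_CONTIG_COLUMNS = ["contig", "median_cn", "n_windows", "mad", "low_evidence"]


def window_cn(corrected_depth: float, baseline_depth: float) -> float:
    """Copy number of one window: ``2 * corrected / baseline``."""
    if not baseline_depth > 0:
        raise ValueError(f"baseline depth must be positive, got {baseline_depth}")
    if corrected_depth < 0:
        raise ValueError(f"negative corrected depth {corrected_depth}")
    return 2.0 * corrected_depth / baseline_depth


def contig_cn(
    cn_values: Sequence[float], min_windows: int = DEFAULT_MIN_WINDOWS
) -> tuple[float, int, float, bool]:
    """Summarize one contig's usable window copy numbers.

    Returns ``(median_cn, n_windows, mad, low_evidence)``. With zero usable
    windows the median and MAD are NaN and the contig is unclassifiable
    downstream. The median of an even count averages the central pair.
    """
    values = np.asarray([v for v in cn_values if not np.isnan(v)], dtype=float)
    n = len(values)
    if n == 0:
        return float("nan"), 0, float("nan"), True
    return (
        float(np.median(values)),
        n,
        float(median_abs_deviation(values)),
        n < min_windows,
    )


@dataclass
class CopyNumberProfile:
    """Window- and contig-level copy numbers for one sample (or sex consensus).

    ``windows`` columns: contig, start, end, excluded, cn.
    ``contigs`` columns: contig, median_cn, n_windows, mad, low_evidence.
    """

    sample_id: str
    sex: str
    windows: pd.DataFrame
    contigs: pd.DataFrame
    baseline_depth: float

    def cn_of(self, contig_id: str) -> float:
        row = self.contigs.loc[self.contigs["contig"] == contig_id]
        if row.empty:
            raise KeyError(f"contig {contig_id!r} not in profile")
        return float(row["median_cn"].iloc[0])

    def to_tsv(self, window_path: str | Path, contig_path: str | Path) -> None:
        self.windows.to_csv(window_path, sep="\t", index=False, float_format="%.6g")
        self.contigs.to_csv(contig_path, sep="\t", index=False, float_format="%.6g")


def _summarize_contigs(windows: pd.DataFrame, min_windows: int) -> pd.DataFrame:
    rows = []
    for contig, grp in windows.groupby("contig", sort=False):
        usable = grp.loc[~grp["excluded"], "cn"]
        rows.append((contig, *contig_cn(usable.to_numpy(), min_windows)))
    return pd.DataFrame(rows, columns=_CONTIG_COLUMNS)


def profile_copy_number(
    corrected: WindowTable,
    model: GCModel,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> CopyNumberProfile:
    """Turn a GC-corrected window table into a copy-number profile.

    The baseline is the model's reference depth (the sample's global
    length-weighted raw mean), which makes copy numbers invariant to an
    overall rescaling of the sample's depth.
    """
    if "corrected_depth" not in corrected.data.columns:
        raise ValueError("window table has no corrected_depth; run correct_depth first")
    baseline = model.reference_depth
    if not baseline > 0:
        raise ValueError(f"baseline depth must be positive, got {baseline}")
    windows = corrected.data[["contig", "start", "end", "excluded"]].copy()
    windows["cn"] = 2.0 * corrected.data["corrected_depth"] / baseline
    return CopyNumberProfile(
        sample_id=corrected.sample_id,
        sex=corrected.sex,
        windows=windows,
        contigs=_summarize_contigs(windows, min_windows),
        baseline_depth=baseline,
    )


def combine_replicates(
    profiles: Sequence[CopyNumberProfile],
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> CopyNumberProfile:
    """Average window copy numbers across same-sex replicates.

    All profiles must share sex and an identical window grid; a window is
    excluded in the consensus iff it is excluded in every replicate.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if len(profiles) == 1:
        return profiles[0]
    sexes = {p.sex for p in profiles}
    if len(sexes) != 1:
        raise ValueError(f"profiles mix sexes {sorted(sexes)}")
    grid0 = profiles[0].windows[["contig", "start", "end"]]
    for p in profiles[1:]:
        if not grid0.equals(p.windows[["contig", "start", "end"]]):
            raise ValueError(
                f"window grids differ between {profiles[0].sample_id!r} "
                f"and {p.sample_id!r}"
            )
    combined = grid0.copy()
    combined["excluded"] = np.logical_and.reduce(
        [p.windows["excluded"].to_numpy() for p in profiles]
    )
    combined["cn"] = np.mean(
        [p.windows["cn"].to_numpy(dtype=float) for p in profiles], axis=0
    )
    combined = combined[_WINDOW_COLUMNS]
    return CopyNumberProfile(
        sample_id="+".join(p.sample_id for p in profiles),
        sex=profiles[0].sex,
        windows=combined,
        contigs=_summarize_contigs(combined, min_windows),
        baseline_depth=float(np.mean([p.baseline_depth for p in profiles])),
    )
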