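"""Classification of contigs as autosomal, X-linked or Y-linked.

The rules read male and female contig copy numbers (diploid scale, cn = 2
for an ordinary autosome) and fire in a fixed order, most specific first:

1. **Y-linked** — single copy in males (|cn_m − 1| ≤ delta_single) and not
   detectable in females (cn_f ≤ absent_max).
2. **X-linked** — at most single-copy-ish in males (cn_m ≤ 1 + delta_single),
   present in females, and a female:male ratio near twofold
   (cn_f / cn_m within ``ratio_x``).
3. **Autosomal** — female:male ratio near 1 and both copy numbers within the
   diploid band [2 − 2·delta_autosome, 2 + 2·delta_autosome].
4. Anything else is **ambiguous**; contigs with no usable windows are
   **unclassifiable**.

Contigs absent in *both* sexes (cn_m = 0) are ambiguous, not Y-linked: the Y
signature requires male presence. Calls are whole-contig; windows on a Y
contig that match X (pseudoautosomal-like segments) are not split out, but a
per-window provisional class dump is available for inspection.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .copy_number import CopyNumberProfile

__all__ = [
    "Linkage",
    "LinkageThresholds",
    "LinkageCall",
    "classify_contig",
    "classify_assembly",
    "window_class_bed",
]


class Linkage(str, enum.Enum):
    AUTOSOMAL = "AUTOSOMAL"
    X_LINKED = "X_LINKED"
    Y_LINKED = "Y_LINKED"
    AMBIGUOUS = "AMBIGUOUS"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


@dataclass(frozen=True)
class LinkageThresholds:
    """Tolerances around the idealized copy-number signatures.

    The field-standard rules state only "single copy", "twofold" and
    "absent"; the widths here make them decidable on noisy estimates and are
    checked for pairwise consistency at construction so no (cn_m, cn_f) can
    satisfy two rules at once.
    """

    delta_single: float = 0.35
    absent_max: float = 0.2
    ratio_x: tuple[float, float] = (1.6, 2.4)
    delta_autosome: float = 0.35

    def __post_init__(self) -> None:
        if not (0 < self.absent_max < 1):
            raise ValueError("absent_max must be in (0, 1)")
        if not (0 < self.delta_single < 1):
            raise ValueError("delta_single must be in (0, 1)")
        if not (0 < self.delta_autosome < 1):
            raise ValueError("delta_autosome must be in (0, 1)")
        lo, hi = self.ratio_x
        if not (1 < lo < hi):
            raise ValueError("ratio_x must satisfy 1 < lo < hi")
        # Rule 1 vs 3: an absent-in-female contig must fall below the diploid band.
        if self.absent_max >= 2 - 2 * self.delta_autosome:
            raise ValueError(
                "absent_max overlaps the autosomal copy-number band; "
                "rules 1 and 3 would not be exclusive"
            )
        # Rule 2 vs 3: the X ratio interval must clear the autosomal ratio band.
        if lo <= 1 + self.delta_autosome:
            raise ValueError(
                "ratio_x lower bound overlaps the autosomal ratio band; "
                "rules 2 and 3 would not be exclusive"
            )


@dataclass(frozen=True)
class LinkageCall:
    contig_id: str
    call: Linkage
    cn_male: float
    cn_female: float
    fm_ratio: float = field(default=float("nan"))
    low_evidence: bool = False


def rule_y(cn_m: np.ndarray, cn_f: np.ndarray, thr: LinkageThresholds) -> np.ndarray:
    """Single copy in males, not detectable in females."""
    return (np.abs(cn_m - 1.0) <= thr.delta_single) & (cn_f <= thr.absent_max)


def rule_x(cn_m: np.ndarray, cn_f: np.ndarray, thr: LinkageThresholds) -> np.ndarray:
    """Present in both sexes with a near-twofold female:male copy ratio."""
    lo, hi = thr.ratio_x
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cn_m > 0, cn_f / np.where(cn_m > 0, cn_m, 1.0), np.nan)
    return (
        (cn_m > 0)
        & (cn_m <= 1.0 + thr.delta_single)
        & (cn_f > thr.absent_max)
        & (ratio >= lo)
        & (ratio <= hi)
    )


def rule_autosome(
    cn_m: np.ndarray, cn_f: np.ndarray, thr: LinkageThresholds
) -> np.ndarray:
    """Equal copy number in both sexes, within the diploid band."""
    band_lo = 2 - 2 * thr.delta_autosome
    band_hi = 2 + 2 * thr.delta_autosome
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cn_m > 0, cn_f / np.where(cn_m > 0, cn_m, 1.0), np.nan)
    return (
        (cn_m > 0)
        & (np.abs(ratio - 1.0) <= thr.delta_autosome)
        & (cn_m >= band_lo)
        & (cn_m <= band_hi)
        & (cn_f >= band_lo)
        & (cn_f <= band_hi)
    )


def classify_pair(
    cn_m: np.ndarray, cn_f: np.ndarray, thr: LinkageThresholds
) -> np.ndarray:
    """Vectorized rule cascade over arrays of (cn_male, cn_female)."""
    cn_m = np.asarray(cn_m, dtype=float)
    cn_f = np.asarray(cn_f, dtype=float)
    out = np.empty(cn_m.shape, dtype=object)
    out[...] = Linkage.AMBIGUOUS
    undef = np.isnan(cn_m) | np.isnan(cn_f)
    is_a = rule_autosome(cn_m, cn_f, thr)
    is_x = rule_x(cn_m, cn_f, thr)
    is_y = rule_y(cn_m, cn_f, thr)
    out[is_a] = Linkage.AUTOSOMAL
    out[is_x] = Linkage.X_LINKED
    out[is_y] = Linkage.Y_LINKED  # Y last in assignment == first in precedence
    out[undef] = Linkage.UNCLASSIFIABLE
    return out


def classify_contig(
    cn_male: float, cn_female: float, thr: LinkageThresholds | None = None
) -> LinkageCall:
    """Classify a single contig from its male and female copy numbers."""
    thr = thr or LinkageThresholds()
    for name, value in (("cn_male", cn_male), ("cn_female", cn_female)):
        if value is not None and not np.isnan(value) and value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
    call = classify_pair(np.array([cn_male]), np.array([cn_female]), thr)[0]
    ratio = cn_female / cn_male if cn_male and cn_male > 0 else float("nan")
    return LinkageCall("", call, cn_male, cn_female, ratio)


def classify_assembly(
    male: CopyNumberProfile,
    female: CopyNumberProfile,
    contig_lengths: Mapping[str, int],
    thr: LinkageThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call every contig of an assembly and summarize bp per class.

    Returns ``(calls, summary)``. ``calls`` has one row per contig with the
    call, both copy numbers, the female:male ratio and evidence flags;
    ``summary`` reports contig count and total bp per class, conserving the
    assembly total.
    """
    thr = thr or LinkageThresholds()
    m_set = set(male.contigs["contig"])
    f_set = set(female.contigs["contig"])
    if m_set != f_set:
        raise ValueError(
            "male/female profiles cover different contigs; "
            f"male-only={sorted(m_set - f_set)} female-only={sorted(f_set - m_set)}"
        )
    missing = m_set - set(contig_lengths)
    if missing:
        raise ValueError(f"no lengths for contigs {sorted(missing)}")

    m = male.contigs.set_index("contig")
    f = female.contigs.set_index("contig")
    order = list(male.contigs["contig"])
    cn_m = m.loc[order, "median_cn"].to_numpy(dtype=float)
    cn_f = f.loc[order, "median_cn"].to_numpy(dtype=float)
    calls = classify_pair(cn_m, cn_f, thr)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cn_m > 0, cn_f / np.where(cn_m > 0, cn_m, 1.0), np.nan)
    low = (
        m.loc[order, "low_evidence"].to_numpy()
        | f.loc[order, "low_evidence"].to_numpy()
    )
    n_win = np.minimum(
        m.loc[order, "n_windows"].to_numpy(), f.loc[order, "n_windows"].to_numpy()
    )
    calls_df = pd.DataFrame(
        {
            "contig": order,
            "call": [c.value for c in calls],
            "cn_male": cn_m,
            "cn_female": cn_f,
            "fm_ratio": ratio,
            "n_windows": n_win,
            "low_evidence": low,
            "length": [contig_lengths[c] for c in order],
        }
    )
    summary_rows = []
    for cls in Linkage:
        sub = calls_df[calls_df["call"] == cls.value]
        summary_rows.append((cls.value, len(sub), int(sub["length"].sum())))
    summary = pd.DataFrame(summary_rows, columns=["class", "n_contigs", "total_bp"])
    return calls_df, summary


def window_class_bed(
    male: CopyNumberProfile,
    female: CopyNumberProfile,
    thr: LinkageThresholds | None = None,
) -> pd.DataFrame:
    """Per-window provisional classes (BED-like), for inspecting mixed contigs."""
    thr = thr or LinkageThresholds()
    grid = male.windows[["contig", "start", "end"]].copy()
    if not grid.equals(female.windows[["contig", "start", "end"]]):
        raise ValueError("male/female window grids differ")
    calls = classify_pair(
        male.windows["cn"].to_numpy(dtype=float),
        female.windows["cn"].to_numpy(dtype=float),
        thr,
    )
    grid["class"] = [c.value for c in calls]
    return grid
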