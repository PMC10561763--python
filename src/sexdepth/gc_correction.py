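"""LOESS correction of GC-dependent depth bias.

Sequencing depth depends systematically on window GC content. We model the
expected depth as a smooth function of GC by locally-weighted linear
regression (tricube weights, degree-1 by default), evaluate it on a fixed GC
grid, and rescale every window's raw depth by ``reference / e(gc)`` so that
the corrected track is flat in GC but keeps the sample's overall level.

Each sample is corrected with its own model: male and female libraries have
different bias. The fit uses all windows — sex-linked windows shift the
depth *level*, not its GC slope, so they perturb the smooth only mildly; an
optional second pass refits on near-diploid windows for users who want the
baseline anchored to autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .depth import WindowTable

__all__ = ["GCModel", "fit_gc_model", "correct_depth", "fit_and_correct"]

MIN_FIT_WINDOWS = 20
#: GC spread below which the fit degenerates to a constant model.
_GC_DEGENERATE_SPAN = 1e-9
#: Fitted values are floored at this fraction of the reference depth.
_FLOOR_FRACTION = 1e-3


@dataclass(frozen=True)
class GCModel:
    """Expected depth as a function of window GC, tabulated on a grid.

    Evaluation linearly interpolates between grid points and clamps outside
    the observed GC range. ``reference_depth`` is the level corrections
    normalize to (the fitting sample's global length-weighted mean).
    """

    span: float
    grid_gc: np.ndarray
    grid_depth: np.ndarray
    reference_depth: float
    degree: int = 1

    def expected(self, gc: np.ndarray | float) -> np.ndarray:
        """Expected depth at ``gc``; NaN GC maps to the reference depth."""
        gc_arr = np.atleast_1d(np.asarray(gc, dtype=float))
        out = np.interp(gc_arr, self.grid_gc, self.grid_depth)
        out = np.where(np.isnan(gc_arr), self.reference_depth, out)
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# span\t{self.span}\n")
            fh.write(f"# reference_depth\t{self.reference_depth:.6g}\n")
            fh.write(f"# degree\t{self.degree}\n")
            fh.write("gc\texpected_depth\n")
            for g, d in zip(self.grid_gc, self.grid_depth):
                fh.write(f"{g:.6f}\t{d:.6f}\n")


def _tricube_kernel_mean(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float
) -> np.ndarray:
    """Degree-0 LOESS: tricube-weighted mean over the span-nearest points."""
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty_like(grid)
    for i, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argpartition(d, min(k, n) - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        if w.sum() == 0:
            w[:] = 1.0
        out[i] = np.average(ys[idx], weights=w)
    return out


def fit_gc_model(
    table: WindowTable,
    span: float = 0.3,
    degree: int = 1,
    grid_points: int = 101,
) -> GCModel:
    """Fit the expected-depth-vs-GC curve on a sample's non-excluded windows.

    Parameters
    ----------
    span:
        Neighborhood width as a fraction of points, in (0, 1].
    degree:
        0 for a tricube kernel mean, 1 (default) for local linear regression.
    grid_points:
        Number of evaluation points spanning the observed GC range.
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    if degree not in (0, 1):
        raise ValueError(f"degree must be 0 or 1, got {degree}")
    rows = table.data[~table.data["excluded"]]
    if len(rows) < MIN_FIT_WINDOWS:
        raise ValueError(
            f"only {len(rows)} usable windows (< {MIN_FIT_WINDOWS}); "
            "use a smaller window size"
        )
    gc = rows["gc"].to_numpy(dtype=float)
    depth = rows["raw_depth"].to_numpy(dtype=float)
    reference = table.global_raw_mean

    if np.ptp(gc) < _GC_DEGENERATE_SPAN:
        grid = np.array([gc.min() - 1e-6, gc.max() + 1e-6])
        return GCModel(span, grid, np.full(2, reference), reference, degree)

    grid = np.linspace(gc.min(), gc.max(), grid_points)
    if degree == 1:
        fitted = lowess(depth, gc, frac=span, it=0, xvals=grid)
    else:
        fitted = _tricube_kernel_mean(gc, depth, grid, span)
    floor = _FLOOR_FRACTION * reference
    fitted = np.maximum(fitted, floor)
    return GCModel(span, grid, fitted, reference, degree)


def correct_depth(table: WindowTable, model: GCModel) -> WindowTable:
    """Append a ``corrected_depth`` column: ``raw * reference / e(gc)``.

    Excluded windows are corrected with the GC value clamped to the model
    range (NaN GC falls back to a unit correction), so every window keeps a
    defined corrected depth.
    """
    data = table.data.copy()
    expected = model.expected(data["gc"].to_numpy(dtype=float))
    data["corrected_depth"] = (
        data["raw_depth"].to_numpy(dtype=float) * model.reference_depth / expected
    )
    return _dc_replace(table, data=data)


def fit_and_correct(
    table: WindowTable,
    span: float = 0.3,
    degree: int = 1,
    two_pass: bool = False,
) -> tuple[WindowTable, GCModel]:
    """Fit a sample's GC model and correct its depths in one call.

    With ``two_pass=True`` the model is refitted on windows whose first-pass
    copy number lies within 25% of diploid (cn in [1.5, 2.5]), anchoring the
    curve to autosome-like windows.
    """
    model = fit_gc_model(table, span=span, degree=degree)
    corrected = correct_depth(table, model)
    if two_pass:
        cn = 2.0 * corrected.data["corrected_depth"] / model.reference_depth
        keep = (~corrected.data["excluded"]) & (cn >= 1.5) & (cn <= 2.5)
        if keep.sum() >= MIN_FIT_WINDOWS:
            sub = _dc_replace(table, data=table.data[keep.to_numpy()].copy())
            model = fit_gc_model(sub, span=span, degree=degree)
            corrected = correct_depth(table, model)
    return corrected, model
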