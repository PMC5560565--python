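"""Validation machinery: exclusion masks, unsigned border position error,
and intra-/inter-rater variability tables.

The retinal layers are ill-defined at the optic nerve head and the scan
periphery, so all comparisons are restricted to an annulus: a 0.3 mm
diameter circle excludes the ONH and a 1.2 mm diameter circle bounds the
periphery.  Radii are computed with the anisotropic lateral spacing; both
annulus boundaries are inclusive (a deterministic rule — boundary pixels at
r = 0.15 mm and r = 0.6 mm belong to the mask).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .volume_io import SurfaceSet, Delineation, delineation_to_surface


@dataclass
class EvalMask:
    """Boolean annulus over the en-face (b, x) grid."""

    mask: np.ndarray
    center_um: tuple[float, float]
    d_inner_mm: float
    d_outer_mm: float

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.mask, dtype=dtype)


def make_eval_mask(shape, spacing, center=None, d_inner_mm: float = 0.3,
                   d_outer_mm: float = 1.2) -> EvalMask:
    """Annular evaluation mask over the en-face grid.

    Parameters
    ----------
    shape
        ``(B, X)`` en-face grid shape (or a 3-D volume shape whose first two
        dims are used).
    spacing
        Voxel spacing ``(lateral_x, bscan_y, axial_z)`` in um.
    center
        Annulus centre ``(b_um, x_um)``; defaults to the grid centre.
    """
    if d_inner_mm >= d_outer_mm:
        raise ValueError("inner diameter must be < outer diameter")
    B, X = shape[0], shape[1]
    sx, sy = spacing[0], spacing[1]
    if center is None:
        center = ((B - 1) / 2 * sy, (X - 1) / 2 * sx)
    cb, cx = center
    bb = np.arange(B) * sy - cb
    xx = np.arange(X) * sx - cx
    r = np.hypot(bb[:, None], xx[None, :])
    mask = (r >= d_inner_mm * 500.0) & (r <= d_outer_mm * 500.0)
    return EvalMask(mask=mask, center_um=(cb, cx),
                    d_inner_mm=d_inner_mm, d_outer_mm=d_outer_mm)


def border_error(a, b, mask, axial_spacing_um: float) -> tuple[float, float]:
    """Unsigned border position error (mean, SD) in micrometres.

    ``a`` and ``b`` are surface position arrays (voxels) on the same grid;
    masked/NaN samples (untraced spans) are excluded pairwise.  Statistics
    are pooled over all masked columns; symmetric in its arguments and
    covariant with the axial spacing.
    """
    a = np.ma.masked_invalid(np.ma.asarray(a, dtype=float))
    b = np.ma.masked_invalid(np.ma.asarray(b, dtype=float))
    m = np.asarray(mask, dtype=bool)
    diff = np.ma.abs(a - b) * axial_spacing_um
    valid = m & ~np.ma.getmaskarray(diff)
    if not valid.any():
        raise ValueError("no valid samples inside the evaluation mask")
    vals = np.asarray(diff[valid])
    return float(vals.mean()), float(vals.std())


def _surface_from_delin(delin: Delineation, surface: str, b: int, X: int):
    recs = [r for r in delin.slices if r["surface"] == surface and int(r["b"]) == b]
    if not recs:
        return None
    return delineation_to_surface(recs[0]["points"], np.arange(X), delin.rule)


def _slicewise_error(sa, sb, row_mask, axial_um):
    """Mean |a-b| um over one B-scan's masked columns; None if empty."""
    a = np.ma.masked_invalid(np.ma.asarray(sa, dtype=float))
    b = np.ma.masked_invalid(np.ma.asarray(sb, dtype=float))
    valid = row_mask & ~np.ma.getmaskarray(a) & ~np.ma.getmaskarray(b)
    if not valid.any():
        return None
    return float(np.mean(np.abs(np.asarray(a[valid]) - np.asarray(b[valid]))) * axial_um)


def variability_tables(delineations: list[Delineation], mask, axial_spacing_um: float,
                       surfaces_auto: SurfaceSet | None = None,
                       surface_names=None) -> dict[str, pd.DataFrame]:
    """Intra-rater, inter-rater and automated-vs-rater error tables.

    Per-slice mean unsigned differences are aggregated as mean +/- SD across
    slices (matching the per-slice structure of rater-variability studies).
    Intra-rater rows pair each rater's repeat tracings of the same B-scan;
    inter-rater rows cover all rater pairs on commonly traced B-scans; when
    ``surfaces_auto`` is given, automated-vs-rater rows are added, using the
    BM as a surrogate for an untraced ONL-Top (the top of the ONL is not
    always visible, hence not always annotated).

    Returns ``{"intra": ..., "inter": ..., "auto": ...}`` DataFrames with
    columns (surface, comparison, n_slices, mean_um, sd_um).
    """
    m = np.asarray(mask, dtype=bool)
    X = m.shape[1]
    if surface_names is None:
        surface_names = sorted({r["surface"] for d in delineations for r in d.slices})

    by_rater: dict[str, list[Delineation]] = {}
    for d in delineations:
        by_rater.setdefault(d.rater, []).append(d)

    def slice_errors(d1, d2, surface, surrogate=False):
        out = []
        bs = sorted({int(r["b"]) for r in d1.slices} & {int(r["b"]) for r in d2.slices})
        for b in bs:
            s1 = _surface_from_delin(d1, surface, b, X)
            s2 = _surface_from_delin(d2, surface, b, X)
            if s2 is None and surrogate and surface == "ONL-Top":
                s2 = _surface_from_delin(d2, "BM", b, X)
            if s1 is None or s2 is None:
                continue
            e = _slicewise_error(s1, s2, m[b], axial_spacing_um)
            if e is not None:
                out.append(e)
        return out

    def agg(rows, errs, surface, comparison):
        if errs:
            rows.append((surface, comparison, len(errs),
                         float(np.mean(errs)), float(np.std(errs))))

    intra_rows = []
    for rater, ds in by_rater.items():
        primaries = [d for d in ds if not d.repeat]
        repeats = [d for d in ds if d.repeat]
        for surface in surface_names:
            errs = []
            for d1 in primaries:
                for d2 in repeats:
                    errs += slice_errors(d1, d2, surface)
            agg(intra_rows, errs, surface, rater)
    if not intra_rows and by_rater:
        warnings.warn("no repeat tracings found; intra-rater table is empty",
                      stacklevel=2)

    inter_rows = []
    for r1, r2 in combinations(sorted(by_rater), 2):
        for surface in surface_names:
            errs = []
            for d1 in by_rater[r1]:
                for d2 in by_rater[r2]:
                    if d1.repeat or d2.repeat:
                        continue
                    errs += slice_errors(d1, d2, surface)
            agg(inter_rows, errs, surface, f"{r1} vs {r2}")

    auto_rows = []
    if surfaces_auto is not None:
        for rater, ds in by_rater.items():
            for surface in surface_names:
                errs = []
                for d in ds:
                    if d.repeat:
                        continue
                    for b in sorted({int(r["b"]) for r in d.slices}):
                        sr = _surface_from_delin(d, surface, b, X)
                        if sr is None and surface == "ONL-Top":
                            sr = _surface_from_delin(d, "BM", b, X)
                        if sr is None or surface not in surfaces_auto.names:
                            continue
                        e = _slicewise_error(surfaces_auto[surface][b], sr,
                                             m[b], axial_spacing_um)
                        if e is not None:
                            errs.append(e)
                agg(auto_rows, errs, surface, f"auto vs {rater}")

    cols = ["surface", "comparison", "n_slices", "mean_um", "sd_um"]
    return {"intra": pd.DataFrame(intra_rows, columns=cols),
            "inter": pd.DataFrame(inter_rows, columns=cols),
            "auto": pd.DataFrame(auto_rows, columns=cols)}
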