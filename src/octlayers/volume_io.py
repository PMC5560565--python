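"""Data model and persistence for OCT volumes, surfaces, and sparse delineations.

Volumes are stored as multi-page TIFF (one page per B-scan) with a JSON
sidecar carrying the voxel spacing and free-form metadata.  Surfaces are
stored as one 32-bit-float TIFF page per surface (values = z in voxels) with
a JSON sidecar listing surface names in anatomical order.  Sparse manual
delineations (control points joined by an interpolating spline) are plain
JSON.

All arrays are indexed ``(b, x, z)`` with ``z = 0`` at the vitreous.
Surface positions are floats in voxel units at their native resolution;
conversion to micrometres happens only in :mod:`octlayers.metrics` and
:mod:`octlayers.stats`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy.interpolate import CubicSpline

#: Anatomical surface order, healthy mouse (10 surfaces, vitreous to sclera).
HEALTHY_SURFACES = (
    "ILM", "RNFGC-IPL", "IPL-INL", "INL-OPL", "OPL-ONL",
    "ELM", "EZ-Top", "EZ-Bottom", "OS-RPE", "BM",
)

#: Anatomical surface order after light damage (6 surfaces).  The
#: photoreceptor band is gone; only the top of the ONL and Bruch's membrane
#: remain below the inner retina.
LD_SURFACES = ("ILM", "RNFGC-IPL", "IPL-INL", "INL-OPL", "ONL-Top", "BM")

SURFACE_ORDER = {"healthy": HEALTHY_SURFACES, "ld": LD_SURFACES}


@dataclass
class OCTVolume:
    """A 3-D SD-OCT intensity volume.

    Parameters
    ----------
    intensity
        Non-negative reals indexed ``(b, x, z)``: B-scan, A-scan, depth.
    spacing
        Voxel spacing ``(lateral_x, bscan_y, axial_z)`` in micrometres per
        voxel; all components strictly positive.
    metadata
        Free-form key/value pairs (scan id, eye, mode, ...).
    """

    intensity: np.ndarray
    spacing: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3 or min(self.intensity.shape) < 1:
            raise ValueError("intensity must be a 3-D (b, x, z) array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


@dataclass
class SurfaceSet:
    """Named axial surfaces ``z = S(b, x)``, ordered vitreous to sclera.

    Surfaces may coincide where a layer has vanished (zero thickness is a
    legal, anatomically meaningful state in the light-damage model).
    """

    surfaces: dict[str, np.ndarray]
    resolution: str = "native"  # "native" | "downsampled"

    def __post_init__(self) -> None:
        self.surfaces = {k: np.asarray(v, dtype=float) for k, v in self.surfaces.items()}
        shapes = {v.shape for v in self.surfaces.values()}
        if len(shapes) > 1:
            raise ValueError(f"surfaces have inconsistent shapes: {shapes}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.surfaces)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def __len__(self) -> int:
        return len(self.surfaces)

    def stack(self) -> np.ndarray:
        """All surfaces as one ``(n_surfaces, B, X)`` array in stored order."""
        return np.stack([self.surfaces[n] for n in self.surfaces])

    def check_ordering(self, atol: float = 1e-9) -> None:
        """Raise if any column violates the anatomical ordering (equality OK)."""
        s = self.stack()
        if np.any(np.diff(s, axis=0) < -atol):
            raise ValueError("surface ordering violated: a later surface lies above an earlier one")


@dataclass
class Delineation:
    """Sparse manual tracing: control points per (surface, B-scan).

    ``slices`` is a list of records ``{"b": int, "surface": str,
    "points": [[x, z], ...]}`` with x strictly increasing and at least two
    control points per traced surface per slice.  ``rule`` selects the
    interpolating spline joining the control points.
    """

    rater: str
    slices: list[dict]
    rule: str = "natural"  # "natural" | "not-a-knot" | "linear"
    repeat: bool = False

    def __post_init__(self) -> None:
        for rec in self.slices:
            pts = np.asarray(rec["points"], dtype=float)
            if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
                raise ValueError(
                    f"slice b={rec.get('b')} surface={rec.get('surface')}: "
                    "need >= 2 control points of form [x, z]"
                )
            if np.any(np.diff(pts[:, 0]) <= 0):
                raise ValueError("control-point x coordinates must be strictly increasing")

    def for_surface(self, surface: str) -> list[dict]:
        return [r for r in self.slices if r["surface"] == surface]

    @property
    def traced_bscans(self) -> list[int]:
        return sorted({r["b"] for r in self.slices})


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def persist_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF (one page per B-scan) + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.intensity, photometric="minisblack")
    sidecar = _sidecar_path(path)
    with open(sidecar, "w") as fh:
        json.dump({"spacing_um": list(volume.spacing), **volume.metadata}, fh, indent=1)
    return path


def load_volume(path: str | Path) -> OCTVolume:
    """Load a volume written by :func:`persist_volume`.

    Round-trips bit-exactly for intensity and exactly for spacing.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}: expected {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    spacing = tuple(meta.pop("spacing_um"))
    intensity = tifffile.imread(path)
    if intensity.ndim == 2:  # single-page TIFF
        intensity = intensity[None]
    if intensity.ndim != 3:
        raise ValueError(f"{path}: expected pages of a single 2-D shape, got ndim={intensity.ndim}")
    return OCTVolume(intensity=intensity, spacing=spacing, metadata=meta)


def persist_surfaces(surfaces: SurfaceSet, path: str | Path) -> Path:
    """One float32 TIFF page per surface + JSON sidecar with ordered names."""
    path = Path(path)
    tifffile.imwrite(path, surfaces.stack().astype(np.float32),
                     photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"surfaces": list(surfaces.names), "resolution": surfaces.resolution}, fh)
    return path


def load_surfaces(path: str | Path) -> SurfaceSet:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}: expected {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    names = meta["surfaces"]
    if arr.shape[0] != len(names):
        raise ValueError(f"{path}: {arr.shape[0]} pages but {len(names)} surface names")
    return SurfaceSet(
        surfaces={n: arr[i].astype(float) for i, n in enumerate(names)},
        resolution=meta.get("resolution", "native"),
    )


def persist_delineation(delin: Delineation, path: str | Path) -> Path:
    with open(path, "w") as fh:
        json.dump(
            {"rater": delin.rater, "rule": delin.rule, "repeat": delin.repeat,
             "slices": [{"b": int(r["b"]), "surface": r["surface"],
                         "points": np.asarray(r["points"], dtype=float).tolist()}
                        for r in delin.slices]},
            fh,
        )
    return Path(path)


def load_delineation(path: str | Path) -> Delineation:
    with open(path) as fh:
        d = json.load(fh)
    return Delineation(rater=d["rater"], slices=d["slices"],
                       rule=d.get("rule", "natural"), repeat=d.get("repeat", False))


# ---------------------------------------------------------------------------
# resolution changes
# ---------------------------------------------------------------------------

def downsample_volume(volume: OCTVolume, lateral_factor: int, axial_factor: int) -> OCTVolume:
    """Block-mean downsampling in the lateral (x) and axial (z) directions.

    The number of B-scans is never altered.  Spacing is multiplied by the
    factors.  Dimensions not divisible by their factor are cropped at the
    trailing edge (with a warning).
    """
    if lateral_factor < 1 or axial_factor < 1:
        raise ValueError("downsampling factors must be >= 1")
    if lateral_factor == 1 and axial_factor == 1:
        return OCTVolume(volume.intensity.copy(), volume.spacing, dict(volume.metadata))
    b, x, z = volume.shape
    xc, zc = x - x % lateral_factor, z - z % axial_factor
    if (xc, zc) != (x, z):
        warnings.warn(
            f"cropping ({x - xc}, {z - zc}) trailing (x, z) voxels to make dims divisible",
            stacklevel=2,
        )
    arr = volume.intensity[:, :xc, :zc].reshape(
        b, xc // lateral_factor, lateral_factor, zc // axial_factor, axial_factor
    )
    out = arr.mean(axis=(2, 4))
    sx, sy, sz = volume.spacing
    return OCTVolume(out, (sx * lateral_factor, sy, sz * axial_factor), dict(volume.metadata))


def rescale_surfaces(surfaces: SurfaceSet, lateral_factor: int, axial_factor: int,
                     native_x: int | None = None) -> SurfaceSet:
    """Bring downsampled surfaces back to native resolution.

    Axial positions are multiplied by ``axial_factor``.  The lateral grid is
    densified by linear interpolation: downsampled column ``i`` maps to
    native column ``i * lateral_factor``; positions past the last mapped
    column are edge-extended.
    """
    if lateral_factor < 1 or axial_factor < 1:
        raise ValueError("rescale factors must be >= 1")
    if lateral_factor == 1 and axial_factor == 1:
        return SurfaceSet({k: v.copy() for k, v in surfaces.surfaces.items()}, "native")
    out: dict[str, np.ndarray] = {}
    for name, s in surfaces.surfaces.items():
        nb, nx = s.shape
        tgt_x = native_x if native_x is not None else nx * lateral_factor
        src = np.arange(nx) * lateral_factor
        grid = np.arange(tgt_x)
        dense = np.empty((nb, tgt_x))
        for i in range(nb):
            dense[i] = np.interp(grid, src, s[i])  # edge-extends beyond src[-1]
        out[name] = dense * axial_factor
    return SurfaceSet(out, "native")


# ---------------------------------------------------------------------------
# delineation -> surface samples
# ---------------------------------------------------------------------------

def _build_spline(points: np.ndarray, rule: str):
    x, z = points[:, 0], points[:, 1]
    if rule == "linear" or len(x) < 3:
        return lambda q: np.interp(q, x, z)
    if rule == "natural":
        return CubicSpline(x, z, bc_type="natural")
    if rule == "not-a-knot":
        return CubicSpline(x, z, bc_type="not-a-knot")
    raise ValueError(f"unknown interpolation rule {rule!r}")


def delineation_to_surface(points: Sequence | np.ndarray, x_grid: np.ndarray,
                           rule: str = "natural") -> np.ma.MaskedArray:
    """Evaluate a control-point tracing on a lateral grid.

    Returns a masked array of axial positions; grid points outside the
    control-point span are marked missing, never extrapolated.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least 2 control points")
    x_grid = np.asarray(x_grid, dtype=float)
    inside = (x_grid >= points[0, 0]) & (x_grid <= points[-1, 0])
    z = np.full(x_grid.shape, np.nan)
    if inside.any():
        z[inside] = _build_spline(points, rule)(x_grid[inside])
    return np.ma.masked_invalid(z)


def delineation_surfaces(delin: Delineation, x_grid: np.ndarray) -> dict[tuple[str, int], np.ma.MaskedArray]:
    """Evaluate every traced (surface, b-scan) of a delineation on ``x_grid``."""
    return {
        (rec["surface"], int(rec["b"])): delineation_to_surface(rec["points"], x_grid, delin.rule)
        for rec in delin.slices
    }
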