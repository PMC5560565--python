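"""Synthetic mouse-retina SD-OCT phantoms with ground truth.

The generator emulates the salient structure of mouse retinal SD-OCT
volumes: a piecewise-layered axial reflectivity profile (hyperreflective
nerve-fibre/plexiform/ellipsoid-zone/RPE bands, hyporeflective nuclear
layers), a central optic-nerve-head depression where all surfaces converge
toward Bruch's membrane, vessel shadows attenuating everything below the
nerve-fibre complex, multiplicative gamma speckle plus additive Gaussian
noise, and per-B-scan axial motion jitter.  In light-damage (``ld``) mode
the outer retina (top of the ONL to Bruch's membrane) is thinned by a
severity fraction that may reach 1.0 — regionally or globally — collapsing
the ONL-Top surface onto the BM.

Ground truth (all surfaces, including every applied motion shift) is
returned alongside the volume, so segmentations can be scored exactly.
Simulated raters place control points on the truth with Gaussian tracing
noise, emulating sparse manual delineation; cohort simulation draws
per-eye layer thicknesses from published group means/SDs for the
longitudinal statistical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import (
    OCTVolume, SurfaceSet, Delineation, HEALTHY_SURFACES, LD_SURFACES,
)

#: Layer mean intensities (arbitrary reflectivity units).  The contrast
#: ordering — bright RNFGC/IPL/OPL/EZ/RPE, dark INL/ONL — matches mouse OCT;
#: the absolute values are free configuration, not measurements.
HEALTHY_INTENSITIES = {
    "vitreous": 10.0,
    "RNFGC": 160.0,     # ILM .. RNFGC-IPL
    "IPL": 120.0,       # RNFGC-IPL .. IPL-INL
    "INL": 60.0,        # IPL-INL .. INL-OPL
    "OPL": 110.0,       # INL-OPL .. OPL-ONL
    "ONL": 50.0,        # OPL-ONL .. ELM
    "IS": 90.0,         # ELM .. EZ-Top (photoreceptor inner segments)
    "EZ": 170.0,        # EZ-Top .. EZ-Bottom
    "OS": 80.0,         # EZ-Bottom .. OS-RPE
    "RPE": 150.0,       # OS-RPE .. BM
    "choroid": 40.0,
}

LD_INTENSITIES = {
    "vitreous": 10.0,
    "RNFGC": 160.0,
    "IPL": 120.0,
    "INL": 60.0,
    "OPL": 90.0,        # INL-OPL .. ONL-Top (residual OPL / edema)
    "ONLPR": 140.0,     # ONL-Top .. BM (remnant outer band)
    "choroid": 40.0,
}

#: Nominal healthy layer thicknesses (micrometres), vitreous to sclera.
#: Chosen to reproduce the control-group magnitudes of the longitudinal
#: study: inner retina 76, outer retina 114, total 190.
HEALTHY_THICKNESSES_UM = {
    "RNFGC": 12.0, "IPL": 39.0, "INL": 25.0, "OPL": 12.0, "ONL": 53.0,
    "IS": 12.0, "EZ": 10.0, "OS": 15.0, "RPE": 12.0,
}

#: Light-damage inner thicknesses; the INL thickens (edema) while the outer
#: band (ONL-Top to BM) is (1 - severity) of the healthy ONL+photoreceptor
#: complex (102 um).
LD_INNER_THICKNESSES_UM = {"RNFGC": 12.0, "IPL": 39.0, "INL": 32.0, "OPL": 10.0}
LD_OUTER_FULL_UM = 102.0


@dataclass
class PhantomParams:
    """Generative parameters of a synthetic scan (defaults = desk scale).

    The default grid is 25 B-scans x 128 A-scans x 512 depths covering
    1.4 x 1.4 mm laterally at the instrument's 0.78 um axial voxel size, a
    laterally downsampled analogue of the full acquisition geometry
    (1000 x 100 x 2048).
    """

    shape: tuple[int, int, int] = (25, 128, 512)
    spacing: tuple[float, float, float] = (1.4e3 / 128, 1.4e3 / 25, 0.78)
    mode: str = "healthy"
    layer_thicknesses_um: dict = field(default_factory=dict)  # overrides
    layer_intensities: dict = field(default_factory=dict)     # overrides
    ilm_depth_um: float = 90.0
    undulation_amplitude_um: float = 4.0
    tilt_um: float = 6.0
    onh_center: tuple[float, float] | None = None  # (b, x) voxels; default centre
    onh_radius_um: float = 120.0
    onh_depth_um: float = 190.0
    n_vessels: int = 6
    vessel_width_px: int = 3
    vessel_attenuation: float = 0.45
    speckle_shape: float = 20.0  # gamma shape; higher = cleaner (frame averaging)
    additive_sigma: float = 4.0
    jitter_sigma_voxels: float = 2.0
    ld_severity: float = 0.75
    ld_ablation_region: tuple | None = None  # ((b0, b1), (x0, x1)), half-open
    ld_taper_px: int = 15

    def __post_init__(self):
        if self.mode not in ("healthy", "ld"):
            raise ValueError(f"mode must be 'healthy' or 'ld', got {self.mode!r}")
        if self.jitter_sigma_voxels < 0:
            raise ValueError("jitter sigma must be >= 0")
        th = self.thicknesses()
        if any(t < 0 for t in th.values()):
            raise ValueError("layer thicknesses must be >= 0")

    def thicknesses(self) -> dict:
        base = dict(HEALTHY_THICKNESSES_UM) if self.mode == "healthy" \
            else {**LD_INNER_THICKNESSES_UM, "ONLPR": (1 - self.ld_severity) * LD_OUTER_FULL_UM}
        base.update(self.layer_thicknesses_um)
        return base

    def intensities(self) -> dict:
        base = dict(HEALTHY_INTENSITIES) if self.mode == "healthy" else dict(LD_INTENSITIES)
        base.update(self.layer_intensities)
        return base


@dataclass
class PhantomTruth:
    """Ground-truth surfaces (native resolution, voxels) + provenance."""

    surfaces: SurfaceSet
    params: PhantomParams
    seed: int


@dataclass
class RaterModel:
    """A simulated human rater placing control points on true surfaces."""

    bias_um: float = 0.0
    sigma_um: float = 1.0
    spacing_px: int = 8
    vessel_behavior: str = "trace_through"  # or "trace_around"

    def __post_init__(self):
        if self.sigma_um < 0:
            raise ValueError("rater sigma must be >= 0")


# layer sequences (layer key between consecutive surfaces, vitreous first)
_HEALTHY_LAYERS = ("RNFGC", "IPL", "INL", "OPL", "ONL", "IS", "EZ", "OS", "RPE")
_LD_LAYERS = ("RNFGC", "IPL", "INL", "OPL", "ONLPR")


def _smooth_field(B, X, amplitude, tilt, rng):
    """Low-frequency undulation + tilt, common to all surfaces (voxel-free units: um)."""
    bb = np.linspace(0, 1, B)[:, None]
    xx = np.linspace(0, 1, X)[None, :]
    f = np.zeros((B, X))
    if amplitude > 0:
        for _ in range(2):
            kx, kb = rng.uniform(0.5, 1.5, 2)
            px, pb = rng.uniform(0, 2 * np.pi, 2)
            f += (amplitude / 2) * np.sin(2 * np.pi * kx * xx + px) * np.cos(2 * np.pi * kb * bb + pb)
    if tilt > 0:
        f += tilt * (rng.uniform(-1, 1) * (xx - 0.5) + rng.uniform(-1, 1) * (bb - 0.5))
    return f


def generate_phantom(params: PhantomParams, seed: int) -> tuple[OCTVolume, PhantomTruth]:
    """Generate a synthetic volume and its ground truth.

    Deterministic given ``(params, seed)``.  Intensity is the layered
    piecewise profile between the truth surfaces (rendered with partial-voxel
    coverage, so integer-positioned flat surfaces give an exactly
    piecewise-constant volume in the noiseless limit), with the
    optic-nerve-head depression, vessel shadows, per-B-scan axial jitter,
    and finally speckle and additive noise.  Truth surfaces include every
    applied shift.
    """
    rng = np.random.default_rng(seed)
    B, X, Z = params.shape
    sx, sy, sz = params.spacing
    th = params.thicknesses()
    inten = params.intensities()
    layers = _HEALTHY_LAYERS if params.mode == "healthy" else _LD_LAYERS
    names = HEALTHY_SURFACES if params.mode == "healthy" else LD_SURFACES

    gaps_um = np.array([th[k] for k in layers], dtype=float)  # (L,)
    gaps = np.broadcast_to(gaps_um[:, None, None], (len(layers), B, X)).copy()

    if params.mode == "ld" and params.ld_ablation_region is not None:
        (b0, b1), (x0, x1) = params.ld_ablation_region
        # ramp severity from the base value to 1.0 over a lateral taper so
        # truth surfaces stay smooth enough for the solver's smoothness bounds
        xg = np.arange(X)
        ramp_x = np.clip(
            np.minimum(xg - (x0 - params.ld_taper_px), (x1 - 1 + params.ld_taper_px) - xg)
            / max(params.ld_taper_px, 1), 0, 1)
        bg_ = np.arange(B)
        ramp_b = np.clip(
            np.minimum(bg_ - (b0 - params.ld_taper_px), (b1 - 1 + params.ld_taper_px) - bg_)
            / max(params.ld_taper_px, 1), 0, 1)
        w = ramp_b[:, None] * ramp_x[None, :]
        sev = params.ld_severity + (1.0 - params.ld_severity) * w
        gaps[-1] = (1.0 - sev) * LD_OUTER_FULL_UM

    # optic-nerve-head depression: remove up to onh_depth_um of tissue,
    # proportionally from every layer, so all surfaces converge toward BM
    cb, cx = params.onh_center if params.onh_center is not None else ((B - 1) / 2, (X - 1) / 2)
    bb = (np.arange(B) - cb) * sy
    xx = (np.arange(X) - cx) * sx
    r2 = bb[:, None] ** 2 + xx[None, :] ** 2
    # steep radial profile with compact support: the pit is fully contained
    # within ~1.15 * onh_radius_um, so layers are untouched in the annulus
    onh = np.exp(-4.0 * (r2 / params.onh_radius_um ** 2) ** 2)
    onh = np.where(onh < 1e-3, 0.0, onh)
    total = gaps.sum(axis=0)
    removed = np.minimum(params.onh_depth_um * onh, total)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total > 0, 1.0 - removed / total, 1.0)
    gaps = gaps * scale[None]

    # surfaces in um depth: BM fixed at ilm_depth + nominal total, layers
    # removed from above (the pit deepens the inner surfaces toward BM)
    base_total = gaps_um.sum()
    bm_um = params.ilm_depth_um + base_total
    undul = _smooth_field(B, X, params.undulation_amplitude_um, params.tilt_um, rng)
    jitter = rng.normal(0.0, params.jitter_sigma_voxels, B) * sz if params.jitter_sigma_voxels > 0 else np.zeros(B)
    shift = undul + jitter[:, None]

    surf_um = np.empty((len(names), B, X))
    surf_um[-1] = bm_um
    for i in range(len(layers) - 1, -1, -1):
        surf_um[i] = surf_um[i + 1] - gaps[i]
    surf_um += shift[None]

    surf_vox = surf_um / sz
    if surf_vox.max() >= Z - 1 or surf_vox.min() <= 1:
        raise ValueError(
            f"layer stack exceeds the axial extent: surfaces span "
            f"[{surf_vox.min():.1f}, {surf_vox.max():.1f}] voxels of {Z}")

    # render: partial-voxel coverage of each layer band
    zg = np.arange(Z, dtype=float)
    img = np.empty((B, X, Z))
    bounds = np.concatenate([
        np.full((1, B, X), -1e6), surf_vox, np.full((1, B, X), 1e6)])
    vals = [inten["vitreous"]] + [inten[k] for k in layers] + [inten["choroid"]]
    img[:] = 0.0
    for k in range(len(vals)):
        lo = bounds[k][:, :, None]
        hi = bounds[k + 1][:, :, None]
        cov = np.clip(np.minimum(hi, zg + 1.0) - np.maximum(lo, zg), 0.0, 1.0)
        img += vals[k] * cov

    # vessel shadows below the RNFGC lower boundary
    if params.n_vessels > 0:
        vx = rng.choice(X - params.vessel_width_px, size=params.n_vessels, replace=False)
        rnfgc_low = surf_vox[1]  # RNFGC-IPL
        for x0v in vx:
            for dx in range(params.vessel_width_px):
                x = x0v + dx
                mask = zg[None, :] > rnfgc_low[:, x, None]
                img[:, x, :] = np.where(mask, img[:, x, :] * params.vessel_attenuation,
                                        img[:, x, :])

    if params.speckle_shape and params.speckle_shape > 0 and np.isfinite(params.speckle_shape):
        img = img * rng.gamma(params.speckle_shape, 1.0 / params.speckle_shape, img.shape)
    if params.additive_sigma > 0:
        img = img + rng.normal(0.0, params.additive_sigma, img.shape)
    img = np.clip(img, 0.0, None)

    volume = OCTVolume(img, params.spacing, {"mode": params.mode, "seed": int(seed)})
    truth = PhantomTruth(
        surfaces=SurfaceSet({n: surf_vox[i] for i, n in enumerate(names)}, "native"),
        params=params, seed=int(seed))
    truth.surfaces.check_ordering()
    return volume, truth


def simulate_rater(truth: PhantomTruth, rater: RaterModel, slice_ids,
                   seed: int, rule: str = "natural", rater_id: str = "sim",
                   visibility_threshold_um: float = 6.0) -> Delineation:
    """Simulate sparse manual delineation of ``truth`` on selected B-scans.

    Control points are the true surface sampled every ``rater.spacing_px``
    lateral voxels, with independent axial noise N(bias, sigma) (micrometres,
    converted to voxels).  Deterministic given ``seed``; repeating with a new
    seed yields an independent tracing for intra-rater experiments.

    Like a human rater, the simulated one does not trace the top of the ONL
    where the residual outer band is thinner than
    ``visibility_threshold_um`` (the layer is not visible there); spans
    with fewer than two visible control points are skipped entirely.
    """
    slice_ids = list(slice_ids)
    if not slice_ids:
        raise ValueError("empty slice list")
    rng = np.random.default_rng(seed)
    sz = truth.params.spacing[2]
    B, X = next(iter(truth.surfaces.surfaces.values())).shape
    xs = np.arange(2, X - 2, rater.spacing_px)
    slices = []
    for b in slice_ids:
        if not (0 <= b < B):
            raise ValueError(f"slice {b} outside volume with {B} B-scans")
        for name in truth.surfaces.names:
            keep = np.ones(len(xs), dtype=bool)
            if name == "ONL-Top" and "BM" in truth.surfaces.names:
                gap_um = (truth.surfaces["BM"][b, xs]
                          - truth.surfaces[name][b, xs]) * sz
                keep = gap_um >= visibility_threshold_um
            ztrue = truth.surfaces[name][b, xs]
            noise_um = rng.normal(rater.bias_um, rater.sigma_um, len(xs))
            z = ztrue + noise_um / sz
            if keep.sum() < 2:
                continue
            slices.append({"b": int(b), "surface": name,
                           "points": np.column_stack([xs[keep], z[keep]]).tolist()})
    return Delineation(rater=rater_id, slices=slices, rule=rule)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _cohort_frame() -> pd.DataFrame:
    """Published group summaries (mean +/- SD um) of eight retinal layer
    thicknesses in control and light-damaged BALB/cJ mice at days 1, 3, 6
    and 9 after light exposure; used as generative parameters."""
    rows = []

    def add(layer, group, vals):
        for day, (m, s) in zip((1, 3, 6, 9), vals):
            if m is not None:
                rows.append((layer, group, day, m, s))

    add("RNFGC", "control", [(11.75, 1.02), (12.17, 0.63), (12.60, 1.05), (12.78, 0.53)])
    add("RNFGC", "ld", [(12.93, 1.10), (12.93, 0.72), (14.23, 1.68), (12.30, 1.77)])
    add("RNFGC+IPL", "control", [(51.30, 2.25), (51.83, 1.93), (52.89, 2.52), (52.05, 2.18)])
    add("RNFGC+IPL", "ld", [(51.75, 0.98), (50.44, 1.46), (50.31, 1.11), (48.24, 0.55)])
    add("IPL", "control", [(39.56, 1.64), (39.73, 1.99), (40.81, 2.56), (39.10, 2.60)])
    add("IPL", "ld", [(38.82, 0.84), (37.50, 1.37), (36.08, 1.37), (35.94, 1.46)])
    add("INL", "control", [(24.40, 0.83), (24.75, 0.59), (24.75, 0.49), (25.11, 0.73)])
    add("INL", "ld", [(32.70, 0.90), (35.22, 0.71), (31.66, 1.14), (30.68, 0.90)])
    add("IR", "control", [(75.71, 3.06), (76.58, 2.37), (77.64, 2.87), (77.16, 2.86)])
    add("IR", "ld", [(84.44, 1.73), (85.66, 2.08), (81.98, 1.52), (78.93, 1.28)])
    add("ONL", "control", [(53.09, 2.42), (52.63, 1.81), (53.46, 1.80), (54.74, 1.84)])
    add("ONL", "ld", [(None, None), (None, None), (25.90, 2.97), (24.08, 2.41)])
    add("OR", "control", [(114.18, 2.10), (112.21, 2.43), (113.08, 1.97), (116.17, 2.10)])
    add("OR", "ld", [(110.88, 3.87), (65.24, 6.68), (36.90, 3.72), (33.61, 4.20)])
    add("TRT", "control", [(189.89, 4.85), (188.78, 4.51), (190.72, 4.80), (193.33, 4.32)])
    add("TRT", "ld", [(195.33, 5.08), (150.90, 7.52), (118.88, 3.32), (112.53, 3.15)])
    return pd.DataFrame(rows, columns=["layer", "group", "day", "mean", "sd"])


#: Group summary table (layer x group x day -> mean, SD in um) parameterising
#: the default cohort simulation.
DEFAULT_COHORT_PARAMS = _cohort_frame()


def generate_cohort(group_means_sds: pd.DataFrame, n_per_group: int,
                    seed: int) -> pd.DataFrame:
    """Draw per-eye layer thicknesses for a simulated cohort.

    ``group_means_sds`` has columns ``layer, group, day, mean, sd`` (um);
    each (layer, group, day) cell yields ``n_per_group`` independent
    Gaussian draws, one per eye (eyes indexed 0..n-1 within each group).
    Deterministic given ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 eyes per group")
    tab = group_means_sds.reset_index(drop=True)
    if (tab["sd"] < 0).any():
        raise ValueError("SD values must be >= 0")
    rng = np.random.default_rng(seed)
    recs = []
    for _, row in tab.iterrows():
        draws = rng.normal(row["mean"], row["sd"], n_per_group)
        for eye, v in enumerate(draws):
            recs.append((eye, row["group"], int(row["day"]), row["layer"], float(v)))
    return pd.DataFrame(recs, columns=["eye", "group", "day", "layer", "thickness_um"])
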