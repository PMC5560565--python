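"""Boundary cost functions for the multi-surface graph solver.

Two families of costs feed the solver:

* plain axial gradient costs (used by the coarse localisation stage, and
  adequate for clean data) — the negated, polarity-signed axial derivative
  of the Gaussian-smoothed volume, shifted to be non-negative;
* machine-learned costs — a multiclass random forest labels each voxel as
  one of the stage's surfaces or as background; the per-surface cost is
  ``1 - P(surface)``.  One forest is trained per stage per mode, and the
  healthy and light-damage model families are fully disjoint.

Per-voxel features: raw intensity, Gaussian-smoothed intensity and signed
axial derivative at three scales, signed axial distance to the coarse ILM
estimate, relative depth within the ILM-to-sclera region of interest, and
normalised lateral position.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .volume_io import OCTVolume, Delineation, delineation_to_surface

#: Default edge polarity of each anatomical surface (direction of the
#: intensity transition when moving from vitreous toward sclera).
DEFAULT_POLARITY = {
    "ILM": "dark_to_bright",
    "RNFGC-IPL": "bright_to_dark",
    "IPL-INL": "bright_to_dark",
    "INL-OPL": "dark_to_bright",
    "OPL-ONL": "bright_to_dark",
    "ELM": "dark_to_bright",
    "EZ-Top": "dark_to_bright",
    "EZ-Bottom": "bright_to_dark",
    "OS-RPE": "dark_to_bright",
    "BM": "bright_to_dark",
    "ONL-Top": "dark_to_bright",
}

FEATURE_RECIPE_ID = "int-grad-s124-roi-v1"
_SCALES = (1.0, 2.0, 4.0)  # axial sigmas, voxels; lateral sigma is half


@dataclass
class CostVolume:
    """Per-surface boundary cost over (a z-window of) a volume.

    ``values`` is ``(B, X, Zw)`` finite, lower = more boundary-like;
    ``z0`` is the window offset into the source volume.
    """

    values: np.ndarray
    z0: int = 0
    surface: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cost volume must be finite")


@dataclass
class FeatureStack:
    """Per-voxel features over the ROI z-window of a working-grid volume."""

    features: np.ndarray  # (n_features, B, X, Zw)
    z0: int
    z1: int
    recipe_id: str = FEATURE_RECIPE_ID

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def window_shape(self) -> tuple[int, int, int]:
        return self.features.shape[1:]

    def matrix(self) -> np.ndarray:
        """Features as an ``(n_voxels, n_features)`` design matrix."""
        return self.features.reshape(self.n_features, -1).T


@dataclass
class BoundaryModel:
    """A trained per-stage boundary classifier.

    ``classes`` is ``("background", *stage_surfaces)`` in anatomical order;
    separate model families are trained for healthy and light-damage scans.
    """

    forest: RandomForestClassifier
    classes: tuple[str, ...]
    recipe_id: str
    mode: str
    stage: int
    seed: int
    oob_accuracy: float


def gradient_cost(volume: OCTVolume, polarity: str, scale: float = 1.0) -> CostVolume:
    """Axial-gradient boundary cost.

    Smooths the intensity with an axial Gaussian of the given sigma
    (voxels), takes the axial derivative signed by ``polarity``
    (positive-going edges for ``"dark_to_bright"``), negates it and shifts
    the result to be non-negative, so minima sit on edges of the requested
    polarity.  Translation-equivariant along z up to edge effects.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    smoothed = ndimage.gaussian_filter1d(volume.intensity.astype(float), scale, axis=2)
    deriv = np.gradient(smoothed, axis=2)
    signed = deriv if polarity == "dark_to_bright" else -deriv
    cost = -signed
    return CostVolume(cost - cost.min())


def extract_features(volume: OCTVolume, roi) -> FeatureStack:
    """Compute the per-voxel feature stack inside the coarse ROI window.

    ``roi`` carries per-column ILM and deep-boundary estimates plus the
    global window ``[z0, z1]`` (see :class:`octlayers.graphseg.ROI`).  The
    relative-depth feature is 0 at the ILM estimate and 1 at the deep
    estimate, clipped to [0, 1].
    """
    z0, z1 = int(roi.z0), int(roi.z1)
    if z1 <= z0:
        raise ValueError("empty ROI window")
    vol = volume.intensity.astype(float)
    B, X, Z = vol.shape
    win = slice(z0, z1 + 1)
    feats = [vol[:, :, win]]
    for s in _SCALES:
        sm = ndimage.gaussian_filter(vol, (0, s / 2, s))
        feats.append(sm[:, :, win])
        feats.append(np.gradient(sm, axis=2)[:, :, win])
    zg = np.arange(z0, z1 + 1, dtype=float)
    dist_ilm = zg[None, None, :] - np.asarray(roi.ilm)[:, :, None]
    denom = np.maximum(np.asarray(roi.deep) - np.asarray(roi.ilm), 1.0)
    rel = np.clip(dist_ilm / denom[:, :, None], 0.0, 1.0)
    xnorm = np.broadcast_to(
        (np.arange(X) / max(X - 1, 1))[None, :, None], dist_ilm.shape)
    feats += [dist_ilm, rel, np.ascontiguousarray(xnorm)]
    return FeatureStack(np.stack(feats), z0=z0, z1=z1)


def _labels_from_delineations(stack: FeatureStack, delineations, stage_surfaces,
                              band: float = 1.0):
    """Voxel labels on traced B-scans, on the working grid.

    A voxel within ``band`` axial voxels of a traced surface is labelled
    with the *nearest* such surface (1-based class index); other ROI voxels
    are background (0).  Where two surfaces coincide (a collapsed layer —
    both tracings run along the same boundary) exact distance ties are
    split deterministically by voxel parity, so both classes keep training
    samples along the shared boundary.
    """
    B, X, Zw = stack.window_shape
    n_s = len(stage_surfaces)
    labels = {}  # b -> (X, Zw) int array
    covered = {name: False for name in stage_surfaces}
    zg = np.arange(Zw, dtype=float)
    for delin in delineations:
        by_b: dict[int, dict[str, np.ma.MaskedArray]] = {}
        for rec in delin.slices:
            name = rec["surface"]
            if name not in stage_surfaces:
                continue
            zs = delineation_to_surface(rec["points"], np.arange(X), delin.rule)
            by_b.setdefault(int(rec["b"]), {})[name] = zs
            covered[name] = True
        for b, traced in by_b.items():
            dist = np.full((n_s, X, Zw), np.inf)
            for name, zs in traced.items():
                k = stage_surfaces.index(name)
                zvals = np.ma.filled(zs, np.nan) - stack.z0
                with np.errstate(invalid="ignore"):
                    d = np.abs(zg[None, :] - zvals[:, None])
                dist[k] = np.where(np.isnan(d), np.inf, d)
            inband = dist <= band
            nearest = np.argmin(dist, axis=0)
            # parity split of exact ties between two coincident surfaces
            dmin = dist.min(axis=0)
            tied = (inband.sum(axis=0) >= 2) & np.isfinite(dmin)
            if tied.any():
                with np.errstate(invalid="ignore"):
                    cands = np.abs(dist - dmin[None]) < 1e-9
                n_tied = cands.sum(axis=0)
                two_way = tied & (n_tied >= 2)
                if two_way.any():
                    first = np.argmax(cands, axis=0)
                    last = n_s - 1 - np.argmax(cands[::-1], axis=0)
                    par = (np.arange(X)[:, None] + np.arange(Zw)[None, :]) % 2
                    nearest = np.where(two_way, np.where(par == 0, first, last),
                                       nearest)
            lab = np.where(inband.any(axis=0), nearest + 1, 0)
            prev = labels.setdefault(b, np.zeros((X, Zw), dtype=int))
            labels[b] = np.where(lab > 0, lab, prev)
    missing = [n for n, ok in covered.items() if not ok]
    if missing:
        raise ValueError(f"no annotations for stage surfaces: {missing}")
    return labels


def train_boundary_classifier(stack: FeatureStack, delineations: list[Delineation],
                              stage: int, stage_surfaces, mode: str, seed: int,
                              n_estimators: int = 100,
                              max_background_ratio: float = 2.0) -> BoundaryModel:
    """Train the multiclass boundary forest for one stage.

    Voxels within +/-1 axial voxel of a delineated surface get that
    surface's label; other ROI voxels on traced B-scans are background,
    subsampled to ``max_background_ratio`` times the mean surface-class
    count (class-balanced sampling).  Deterministic given ``seed``;
    out-of-bag accuracy is recorded on the model.
    """
    stage_surfaces = tuple(stage_surfaces)
    labels = _labels_from_delineations(stack, delineations, stage_surfaces)
    B, X, Zw = stack.window_shape
    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for b, lab in sorted(labels.items()):
        feat = stack.features[:, b].reshape(stack.n_features, -1).T  # (X*Zw, nf)
        lab = lab.reshape(-1)
        Xs.append(feat)
        ys.append(lab)
    Xall = np.vstack(Xs)
    yall = np.concatenate(ys)
    classes_present = np.unique(yall)
    if len(classes_present) < 2:
        raise ValueError("training labels contain a single class; need >= 2")
    surf_counts = [(yall == k).sum() for k in range(1, len(stage_surfaces) + 1)]
    n_bg_keep = int(max_background_ratio * np.mean([c for c in surf_counts if c > 0]))
    bg_idx = np.nonzero(yall == 0)[0]
    keep = np.ones(len(yall), dtype=bool)
    if len(bg_idx) > n_bg_keep:
        drop = rng.choice(bg_idx, size=len(bg_idx) - n_bg_keep, replace=False)
        keep[drop] = False
    Xtr, ytr = Xall[keep], yall[keep]
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=int(seed) % (2 ** 32),
        oob_score=True, n_jobs=1)
    forest.fit(Xtr, ytr)
    return BoundaryModel(
        forest=forest, classes=("background",) + stage_surfaces,
        recipe_id=stack.recipe_id, mode=mode, stage=stage, seed=int(seed),
        oob_accuracy=float(forest.oob_score_))


def predict_costs(model: BoundaryModel, stack: FeatureStack) -> list[CostVolume]:
    """Per-surface cost volumes ``1 - P(surface)`` over the ROI window.

    The affine probability-to-cost map keeps costs bounded in [0, 1]
    (``-log P`` would introduce infinities at P = 0).  Returns one
    :class:`CostVolume` per stage surface, in anatomical order.
    """
    if model.recipe_id != stack.recipe_id:
        raise ValueError(
            f"feature recipe mismatch: model={model.recipe_id!r}, "
            f"stack={stack.recipe_id!r}")
    proba = model.forest.predict_proba(stack.matrix())
    shape = stack.window_shape
    out = []
    fitted = list(model.forest.classes_)
    for k, name in enumerate(model.classes[1:], start=1):
        if k in fitted:
            p = proba[:, fitted.index(k)]
        else:  # class absent from training (should not happen in practice)
            p = np.zeros(proba.shape[0])
        out.append(CostVolume((1.0 - p).reshape(shape), z0=stack.z0, surface=name))
    return out


# ---------------------------------------------------------------------------
# model persistence: one file = JSON header line + pickled forest
# ---------------------------------------------------------------------------

def save_model(model: BoundaryModel, path) -> Path:
    path = Path(path)
    header = {
        "classes": list(model.classes), "recipe_id": model.recipe_id,
        "mode": model.mode, "stage": model.stage, "seed": model.seed,
        "oob_accuracy": model.oob_accuracy,
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n")
        fh.write(pickle.dumps(model.forest))
    return path


def load_model(path) -> BoundaryModel:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        forest = pickle.loads(fh.read())
    return BoundaryModel(
        forest=forest, classes=tuple(header["classes"]),
        recipe_id=header["recipe_id"], mode=header["mode"],
        stage=int(header["stage"]), seed=int(header["seed"]),
        oob_accuracy=float(header["oob_accuracy"]))
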