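"""Exact constrained multi-surface segmentation via a single minimum s-t cut.

The terrain-like problem: find, for each of ``S`` ordered surfaces and each
image column ``(b, x)``, an axial position ``z`` minimising the summed
per-voxel boundary cost, subject to hard constraints —

* smoothness: ``|S(b, x) - S(b, x')| <= smoothness_x`` for laterally adjacent
  columns, and ``<= smoothness_b`` between adjacent B-scans (relaxed relative
  to the lateral bound, to tolerate axial motion between B-scans);
* interaction: for an ordered pair (upper, lower),
  ``min_sep <= S_lower - S_upper <= max_sep`` in every column.  A
  ``min_sep`` of zero allows the two surfaces to coincide, which is how a
  vanished layer (e.g. the outer nuclear layer after light damage)
  collapses to zero thickness.

The feasible configurations form a lattice and the objective is modular, so
the set of optima is closed under the pointwise minimum; we return that
pointwise-minimal optimum (computed as the source-minimal minimum cut),
which realises the documented tie-break: ties are broken toward smaller z,
then toward the earlier surface.

The graph is the standard closure/"project-selection" construction: one node
per (surface, column, z) with transformed weight ``w(z) = c(z) - c(z-1)``,
infinite intra-column, smoothness and interaction arcs, and a heavily
negative base row forcing a nonempty closure.  Costs are solved in 64-bit
fixed point (integer inputs exactly; float inputs quantised at 2**-30 of a
cost unit).
"""

from __future__ import annotations

import math
import time
import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import maximum_flow, breadth_first_order

from .volume_io import (
    OCTVolume, SurfaceSet, Delineation, downsample_volume, rescale_surfaces,
    SURFACE_ORDER,
)
from . import costs as costs_mod

logger = logging.getLogger(__name__)

_INT32_CAP = 2 ** 31 - 16  # scipy's max-flow works in 32-bit capacities
_ROI_PENALTY = 8.0  # per violating column, in units of the normalised cost range


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSpec:
    """Hard feasibility constraints for one simultaneous solve.

    Parameters
    ----------
    smoothness_x, smoothness_b
        Maximum |Delta z| (voxels) between laterally adjacent columns /
        adjacent B-scans, one value per surface (or a scalar broadcast to
        all surfaces).
    pairs
        ``(upper_index, lower_index, min_sep, max_sep)`` separation bounds in
        voxels for ordered surface pairs; ``max_sep=None`` means unbounded.
    """

    smoothness_x: list[int] | int
    smoothness_b: list[int] | int
    pairs: list[tuple[int, int, int, int | None]] = field(default_factory=list)

    def resolved(self, n_surfaces: int, depth: int):
        sx = self.smoothness_x
        sb = self.smoothness_b
        sx = [int(sx)] * n_surfaces if np.isscalar(sx) else [int(v) for v in sx]
        sb = [int(sb)] * n_surfaces if np.isscalar(sb) else [int(v) for v in sb]
        if len(sx) != n_surfaces or len(sb) != n_surfaces:
            raise ValueError("smoothness lists must have one entry per surface")
        if any(v < 0 for v in sx + sb):
            raise ValueError("smoothness bounds must be >= 0")
        pairs = []
        for (u, l, m, M) in self.pairs:
            M = depth if M is None else int(M)
            m = int(m)
            if m < 0:
                raise ValueError(f"min_sep must be >= 0 for pair ({u}, {l})")
            if m > M:
                raise ValueError(f"min_sep > max_sep for pair ({u}, {l})")
            if not (0 <= u < n_surfaces and 0 <= l < n_surfaces):
                raise ValueError(f"pair ({u}, {l}) out of range")
            pairs.append((int(u), int(l), m, M))
        return sx, sb, pairs


def _propagate_bounds(n_surfaces: int, depth: int, pairs) -> tuple[np.ndarray, np.ndarray]:
    """Tightest per-surface z ranges implied by the separation constraints."""
    lo = np.zeros(n_surfaces, dtype=int)
    hi = np.full(n_surfaces, depth - 1, dtype=int)
    for _ in range(n_surfaces * max(1, len(pairs)) + 1):
        changed = False
        for (u, l, m, M) in pairs:
            cand = lo[u] + m
            if cand > lo[l]:
                lo[l] = cand; changed = True
            cand = hi[l] - m
            if cand < hi[u]:
                hi[u] = cand; changed = True
            cand = lo[l] - M
            if cand > lo[u]:
                lo[u] = cand; changed = True
            cand = hi[u] + M
            if cand < hi[l]:
                hi[l] = cand; changed = True
        if not changed:
            break
    if np.any(lo > hi):
        bad = int(np.argmax(lo > hi))
        raise ValueError(
            f"infeasible constraints: surface {bad} has empty z range "
            f"[{lo[bad]}, {hi[bad]}] for depth {depth}"
        )
    return lo, hi


def _as_cost_arrays(costs) -> np.ndarray:
    arrs = []
    for c in costs:
        a = c.values if hasattr(c, "values") else np.asarray(c)
        arrs.append(np.asarray(a))
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"cost volumes have inconsistent shapes: {shapes}")
    a0 = arrs[0]
    if a0.ndim != 3:
        raise ValueError("cost volumes must be 3-D (b, x, z)")
    stack = np.stack(arrs)
    if not np.all(np.isfinite(stack)):
        raise ValueError("cost volumes must be finite")
    return stack


def _column_pos_total(stack: np.ndarray) -> int:
    """Sum of positive axial increments — the graph's total sink capacity."""
    d = np.diff(stack, axis=-1)
    return int(np.maximum(d, 0).sum())


def _to_fixed_point(stack: np.ndarray) -> np.ndarray:
    """Quantise costs so every derived capacity fits scipy's 32-bit budget.

    Integer costs are used as-is when the base-forcing constant fits
    (exact solve); float costs are normalised to [-1, 1] (a global positive
    scaling never changes the optimiser) and quantised at the largest
    fixed-point scale whose capacities stay within 32 bits.
    """
    if np.issubdtype(stack.dtype, np.integer):
        out = stack.astype(np.int64)
        if _fixed_point_budget(out) < _INT32_CAP:
            return out
        stack = stack.astype(float)
    m = np.abs(stack).max()
    unit = stack / m if m > 0 else stack.astype(float)
    budget = _column_pos_total_f(unit) + 2.0
    scale = max(1.0, 0.45 * _INT32_CAP / budget)
    while True:
        q = np.rint(unit * scale).astype(np.int64)
        if _fixed_point_budget(q) < _INT32_CAP:
            return q
        scale /= 2.0
        if scale < 1.0:
            raise ValueError("cost volume too irregular for 32-bit fixed point")


def _fixed_point_budget(q: np.ndarray) -> int:
    """Largest capacity the graph built from integer costs ``q`` can hold
    (the base source arc: L - min c, with L = pos_total + max c + 1)."""
    return (_column_pos_total(q) + max(0, int(q.max()))
            + max(0, -int(q.min())) + 2)


def _column_pos_total_f(stack: np.ndarray) -> float:
    d = np.diff(stack, axis=-1)
    return float(np.maximum(d, 0).sum())


# ---------------------------------------------------------------------------
# exact solver
# ---------------------------------------------------------------------------

def segment_surfaces(costs, constraints: ConstraintSpec, names=None,
                     column_floor: np.ndarray | None = None,
                     column_ceil: np.ndarray | None = None):
    """Globally optimal simultaneous multi-surface segmentation.

    Parameters
    ----------
    costs
        One ``(B, X, Z)`` cost array (or :class:`~octlayers.costs.CostVolume`)
        per surface, in anatomical order (vitreous side first); lower cost =
        more boundary-like.
    constraints
        Smoothness and pairwise-separation bounds (voxels).
    names
        Optional surface names; when given a :class:`SurfaceSet` is returned,
        otherwise an integer ``(S, B, X)`` position array.
    column_floor, column_ceil
        Optional per-column ``(B, X)`` soft z bounds applied to all surfaces
        of the solve (used to confine a stage to the region of interest); the
        bounds are enforced through a large finite penalty, so they never make
        the problem infeasible.

    Returns the exact global minimiser of the total cost; among equal-cost
    optima the pointwise-minimal one (smaller z, then earlier surface).
    """
    raw = _as_cost_arrays(costs)
    n_surf, B, X, Z = raw.shape
    sx, sb, pairs = constraints.resolved(n_surf, Z)
    lo, hi = _propagate_bounds(n_surf, Z, pairs)

    # per-column ROI bounds as a finite penalty on the normalised costs: a
    # configuration pays _ROI_PENALTY (several times the whole cost range)
    # per violating column, so violations only occur if the bounds admit no
    # reasonable configuration at all
    if column_floor is not None or column_ceil is not None:
        m = np.abs(raw).max()
        unit = raw.astype(float) / m if m > 0 else raw.astype(float)
        zz = np.arange(Z)
        mask = np.zeros((B, X, Z), dtype=bool)
        if column_floor is not None:
            mask |= zz[None, None, :] < np.asarray(column_floor)[:, :, None]
        if column_ceil is not None:
            mask |= zz[None, None, :] > np.asarray(column_ceil)[:, :, None]
        raw = unit + _ROI_PENALTY * mask[None]
    stack = _to_fixed_point(raw)

    ncol = B * X
    depths = hi - lo + 1
    n_nodes = int((depths * ncol).sum())
    base = np.concatenate([[0], np.cumsum(depths * ncol)])[:-1]

    def ids(s):  # (ncol, depth_s) node ids of surface s
        return (base[s] + np.arange(ncol * depths[s])).reshape(ncol, depths[s])

    # transformed node weights
    w_parts, src_e, snk_e, src_c, snk_c = [], [], [], [], []
    pos_total = 0
    col_c = stack.reshape(n_surf, ncol, Z)
    for s in range(n_surf):
        c = col_c[s][:, lo[s]:hi[s] + 1]
        w = np.empty_like(c)
        w[:, 1:] = np.diff(c, axis=1)
        w[:, 0] = 0  # placeholder; base weight set below
        pos_total += int(np.maximum(w[:, 1:], 0).sum())
        w_parts.append((c, w))
    # L must (a) make every base weight negative and (b) make any nonempty
    # closure cheaper than the empty one: column totals are c(z) - L, so
    # L > max c suffices for (b) given the base layer is negative overall
    L = pos_total + max(0, int(stack.max())) + 1
    for s in range(n_surf):
        c, w = w_parts[s]
        w[:, 0] = c[:, 0] - L  # force every base node into the closure
        wf = w.reshape(-1)
        idf = ids(s).reshape(-1)
        neg = wf < 0
        pos = wf > 0
        src_e.append(idf[neg]); src_c.append(-wf[neg])
        snk_e.append(idf[pos]); snk_c.append(wf[pos])

    INF = pos_total + 1  # min cut <= all-to-sink cut = pos_total, so never saturated

    inf_rows, inf_cols = [], []

    def add_shifted(src_ids, tgt_ids, shift, s_tgt):
        # src node at z implies tgt node at clip(z - shift, base)
        d = tgt_ids.shape[1]
        zt = np.clip(np.arange(src_ids.shape[1]) - shift, 0, d - 1)
        inf_rows.append(src_ids.reshape(-1))
        inf_cols.append(tgt_ids[:, zt].reshape(-1))

    for s in range(n_surf):
        sid = ids(s)
        # intra-column downward arcs
        inf_rows.append(sid[:, 1:].reshape(-1))
        inf_cols.append(sid[:, :-1].reshape(-1))
        # smoothness arcs on the (B, X) grid
        g = sid.reshape(B, X, depths[s])
        for delta, axis in ((sx[s], 1), (sb[s], 0)):
            for a, t in (((slice(1, None)), (slice(None, -1))),
                         ((slice(None, -1)), (slice(1, None)))):
                sl_a = [slice(None)] * 2; sl_t = [slice(None)] * 2
                sl_a[axis], sl_t[axis] = a, t
                ga = g[tuple(sl_a)].reshape(-1, depths[s])
                gt = g[tuple(sl_t)].reshape(-1, depths[s])
                add_shifted(ga, gt, delta, s)
    for (u, l, m, M) in pairs:
        uid, lid = ids(u), ids(l)
        # S_l >= S_u + m : node (u, z) implies (l, z + m); in range-local
        # coordinates the shift is -(m + lo[u] - lo[l])
        add_shifted(uid, lid, -(m + lo[u] - lo[l]), l)
        # S_u >= S_l - M
        add_shifted(lid, uid, M - lo[l] + lo[u], u)

    src, snk = n_nodes, n_nodes + 1
    e_src = np.concatenate(src_e) if src_e else np.empty(0, int)
    c_src = np.concatenate(src_c) if src_c else np.empty(0, np.int64)
    e_snk = np.concatenate(snk_e) if snk_e else np.empty(0, int)
    c_snk = np.concatenate(snk_c) if snk_c else np.empty(0, np.int64)
    r_inf = np.concatenate(inf_rows)
    c_inf = np.concatenate(inf_cols)
    keep = r_inf != c_inf  # drop self-loops from clamped arcs
    r_inf, c_inf = r_inf[keep], c_inf[keep]

    all_rows = np.concatenate([np.full(len(e_src), src), e_snk, r_inf])
    all_cols = np.concatenate([e_src, np.full(len(e_snk), snk), c_inf])
    all_caps = np.concatenate([c_src, c_snk, np.full(len(r_inf), INF, np.int64)])

    t0 = time.time()
    A = coo_matrix((all_caps, (all_rows, all_cols)),
                   shape=(n_nodes + 2, n_nodes + 2)).tocsr()
    A.sum_duplicates()
    # duplicate structural arcs may sum above the 32-bit budget; re-clip
    A.data = np.minimum(A.data, _INT32_CAP)
    A = A.astype(np.int32)
    res = maximum_flow(A, src, snk)
    # source-minimal cut = minimal closure = pointwise-minimal optimum
    resid = A - res.flow
    resid.data = (resid.data > 0).astype(np.int64)
    resid.eliminate_zeros()
    order = breadth_first_order(resid, src, return_predecessors=False)
    selected = np.zeros(n_nodes + 2, dtype=bool)
    selected[order] = True
    logger.debug("maxflow: %d nodes, %d arcs, %.2fs", n_nodes, A.nnz, time.time() - t0)

    out = np.empty((n_surf, B, X), dtype=int)
    for s in range(n_surf):
        cnt = selected[ids(s)].sum(axis=1)
        out[s] = (lo[s] + cnt - 1).reshape(B, X)
    if names is not None:
        return SurfaceSet({n: out[i].astype(float) for i, n in enumerate(names)})
    return out


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_segment(costs, constraints: ConstraintSpec, names=None,
                        max_configs: int = 10 ** 7):
    """Exhaustive-enumeration oracle with the solver's tie-break.

    Enumerates every feasible configuration (infeasible branches pruned,
    plus an admissible lower-bound prune that can never discard an optimum),
    collects all minimum-cost configurations, and returns their pointwise
    minimum — which, by the lattice property of the feasible set, is itself
    an optimum.  Intended for tiny instances only.
    """
    stack = _as_cost_arrays(costs).astype(float)
    n_surf, B, X, Z = stack.shape
    sx, sb, pairs = constraints.resolved(n_surf, Z)
    lo, hi = _propagate_bounds(n_surf, Z, pairs)

    ncol = B * X
    col_costs = stack.reshape(n_surf, ncol, Z)

    # feasible per-column joint tuples
    ranges = [range(lo[s], hi[s] + 1) for s in range(n_surf)]
    tuples = []
    for combo in product(*ranges):
        ok = all(m <= combo[l] - combo[u] <= M for (u, l, m, M) in pairs)
        if ok:
            tuples.append(combo)
    if not tuples:
        raise ValueError("infeasible constraints: no per-column configuration exists")
    if len(tuples) ** ncol > max_configs:
        raise ValueError(
            f"instance too large for brute force: {len(tuples)}^{ncol} configurations"
        )
    tuples_arr = np.array(tuples)  # (T, n_surf)
    tup_cost = np.array([
        sum(col_costs[s, :, t[s]] for s in range(n_surf))  # (ncol,) per tuple
        for t in tuples
    ])  # (T, ncol)
    col_min = tup_cost.min(axis=0)  # admissible remaining-cost bound

    # raster order; neighbours already assigned: left (same b) and up (b-1)
    def neighbours(col):
        b, x = divmod(col, X)
        out = []
        if x > 0:
            out.append((col - 1, sx))
        if b > 0:
            out.append((col - X, sb))
        return out

    nbrs = [neighbours(c) for c in range(ncol)]
    suffix_min = np.concatenate([np.cumsum(col_min[::-1])[::-1], [0.0]])

    best_cost = math.inf
    best_configs: list[tuple] = []
    assign = [0] * ncol  # tuple indices

    def rec(col, acc):
        nonlocal best_cost, best_configs
        if col == ncol:
            if acc < best_cost - 1e-12:
                best_cost = acc
                best_configs = [tuple(assign)]
            elif acc <= best_cost + 1e-12:
                best_configs.append(tuple(assign))
            return
        if acc + suffix_min[col] > best_cost + 1e-12:
            return
        for ti in range(len(tuples)):
            t = tuples_arr[ti]
            ok = True
            for (ncol_idx, smooth) in nbrs[col]:
                tn = tuples_arr[assign[ncol_idx]]
                for s in range(n_surf):
                    if abs(int(t[s]) - int(tn[s])) > smooth[s]:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            assign[col] = ti
            rec(col + 1, acc + tup_cost[ti, col])
        return

    rec(0, 0.0)
    if not best_configs:
        raise ValueError("infeasible constraints: no configuration satisfies smoothness")

    configs = np.array([[tuples_arr[ti] for ti in cfg] for cfg in best_configs])
    meet = configs.min(axis=0)  # (ncol, n_surf); lattice meet of all optima
    out = meet.T.reshape(n_surf, B, X)
    if names is not None:
        return SurfaceSet({n: out[i].astype(float) for i, n in enumerate(names)})
    return out


# ---------------------------------------------------------------------------
# coarse ROI localisation
# ---------------------------------------------------------------------------

@dataclass
class ROI:
    """Coarse region of interest: per-column ILM / deep-boundary estimates
    (in voxels of the working grid) and the global z window [z0, z1]."""

    ilm: np.ndarray
    deep: np.ndarray
    z0: int
    z1: int

    @property
    def depth(self) -> int:
        return self.z1 - self.z0 + 1


def coarse_localize(volume: OCTVolume, margin_above_um: float = 20.0,
                    margin_below_um: float = 40.0,
                    min_sep_um: float = 60.0, max_sep_um: float = 280.0,
                    grad_scale: float = 1.0) -> ROI:
    """Locate the retina in a working-resolution volume.

    Downsamples by a further factor of 4 (lateral and axial), segments the
    ILM (dark-to-bright) and a deep bright-to-dark boundary (the outer
    retina / choroid transition) simultaneously with gradient costs, then
    rescales the two surfaces back to the working grid.  The returned ROI is
    ``[ILM - margin_above, deep + margin_below]``; all subsequent stages are
    confined to it.  The deep boundary is an auxiliary estimate only and is
    never reported as an anatomical surface.
    """
    vol4 = downsample_volume(volume, 4, 4)
    sz = vol4.spacing[2]
    c_ilm = costs_mod.gradient_cost(vol4, "dark_to_bright", grad_scale)
    c_deep = costs_mod.gradient_cost(vol4, "bright_to_dark", grad_scale)
    Z4 = vol4.shape[2]
    spec = ConstraintSpec(
        smoothness_x=2, smoothness_b=3,
        pairs=[(0, 1, max(1, round(min_sep_um / sz)),
                min(Z4 - 1, round(max_sep_um / sz)))],
    )
    pos = segment_surfaces([c_ilm.values, c_deep.values], spec)
    ss = rescale_surfaces(
        SurfaceSet({"ilm": pos[0].astype(float), "deep": pos[1].astype(float)},
                   "downsampled"),
        4, 4, native_x=volume.shape[1],
    )
    sz_work = volume.spacing[2]
    ilm = ss["ilm"] - margin_above_um / sz_work
    deep = ss["deep"] + margin_below_um / sz_work
    Z = volume.shape[2]
    z0 = int(np.clip(np.floor(ilm.min()), 0, Z - 2))
    z1 = int(np.clip(np.ceil(deep.max()), z0 + 1, Z - 1))
    return ROI(ilm=np.clip(ilm, 0, Z - 1), deep=np.clip(deep, 0, Z - 1), z0=z0, z1=z1)


# ---------------------------------------------------------------------------
# stage plans
# ---------------------------------------------------------------------------

#: Nominal healthy layer gaps between consecutive surfaces (micrometres);
#: separation constraints default to the nominal value +/- 50 %.
NOMINAL_GAPS_UM = {
    ("ILM", "RNFGC-IPL"): 12.0,
    ("RNFGC-IPL", "IPL-INL"): 39.0,
    ("IPL-INL", "INL-OPL"): 25.0,
    ("INL-OPL", "OPL-ONL"): 12.0,
    ("OPL-ONL", "ELM"): 53.0,
    ("ELM", "EZ-Top"): 12.0,
    ("EZ-Top", "EZ-Bottom"): 10.0,
    ("EZ-Bottom", "OS-RPE"): 15.0,
    ("OS-RPE", "BM"): 12.0,
    # light-damage mode
    ("INL-OPL", "ONL-Top"): 10.0,
}

HEALTHY_STAGES = (
    ("ILM", "RNFGC-IPL"),
    ("IPL-INL", "INL-OPL", "OPL-ONL"),
    ("ELM", "EZ-Top", "EZ-Bottom", "OS-RPE", "BM"),
)
LD_STAGES = (
    ("ILM", "RNFGC-IPL"),
    ("IPL-INL", "INL-OPL"),
    ("ONL-Top", "BM"),
)


@dataclass
class Stage:
    surfaces: tuple[str, ...]
    constraints: ConstraintSpec


@dataclass
class StagePlan:
    """Ordered stages of the three-step segmentation for one mode."""

    mode: str
    stages: list[Stage]

    @property
    def all_surfaces(self) -> tuple[str, ...]:
        return tuple(n for st in self.stages for n in st.surfaces)


def _stage_constraints(surfs: tuple[str, ...], axial_um: float, mode: str,
                       smoothness_x: int, smoothness_b: int) -> ConstraintSpec:
    pairs = []
    for i in range(len(surfs) - 1):
        u, l = surfs[i], surfs[i + 1]
        if mode == "ld" and (u, l) == ("ONL-Top", "BM"):
            # the photoreceptor band may vanish entirely after light damage
            pairs.append((i, i + 1, 0, round(1.5 * 102.0 / axial_um)))
            continue
        nominal = NOMINAL_GAPS_UM[(u, l)]
        pairs.append((i, i + 1,
                      max(1, round(0.5 * nominal / axial_um)),
                      max(2, round(1.5 * nominal / axial_um))))
    return ConstraintSpec(smoothness_x=smoothness_x, smoothness_b=smoothness_b,
                          pairs=pairs)


def build_plan(mode: str, axial_um: float, smoothness_x: int = 2,
               smoothness_b: int = 6) -> StagePlan:
    """Default three-stage plan; all constraint values are configuration.

    ``axial_um`` is the axial voxel size of the working (2x-downsampled)
    grid, used to convert the micrometre separation defaults to voxels.
    The inter-B-scan smoothness bound is deliberately larger than the
    lateral one, absorbing axial motion between B-scans.
    """
    stage_defs = HEALTHY_STAGES if mode == "healthy" else LD_STAGES
    if mode not in ("healthy", "ld"):
        raise ValueError(f"mode must be 'healthy' or 'ld', got {mode!r}")
    stages = [
        Stage(surfs, _stage_constraints(surfs, axial_um, mode,
                                        smoothness_x, smoothness_b))
        for surfs in stage_defs
    ]
    return StagePlan(mode=mode, stages=stages)


def healthy_plan(axial_um: float, **kw) -> StagePlan:
    return build_plan("healthy", axial_um, **kw)


def ld_plan(axial_um: float, **kw) -> StagePlan:
    return build_plan("ld", axial_um, **kw)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

GUARD_VOXELS = 2  # stage-to-stage overlap allowance at working resolution
ONL_VISIBILITY_P = 0.6  # regional column-max P(ONL-Top) below this = "not visible"


def _stage_costs(volume: OCTVolume, stack, model, stage: Stage, roi: ROI):
    if model == "gradient":
        out = []
        for name in stage.surfaces:
            cv = costs_mod.gradient_cost(
                volume, costs_mod.DEFAULT_POLARITY[name], 1.0)
            out.append(cv.values[:, :, roi.z0:roi.z1 + 1])
        return out
    cvs = costs_mod.predict_costs(model, stack)
    want = list(stage.surfaces)
    have = [c.surface for c in cvs]
    if have != want:
        raise ValueError(f"stage/model mismatch: model predicts {have}, stage needs {want}")
    return [c.values for c in cvs]


def segment_retina(volume: OCTVolume, mode: str, models=None,
                   plan: StagePlan | None = None,
                   lateral_factor: int = 2, axial_factor: int = 2) -> SurfaceSet:
    """Run the full three-stage segmentation on a native-resolution volume.

    Pipeline: downsample by 2 laterally and axially (B-scan count unchanged)
    -> coarse ROI localisation -> three simultaneous-solve stages, each
    confined below the previous stage's lowest surface (minus a small guard
    band) -> rescale all surfaces to native resolution.

    ``models`` maps stage index -> trained :class:`BoundaryModel`, or the
    string ``"gradient"`` for plain gradient costs; ``None`` uses gradient
    costs for every stage (adequate on low-noise data only).

    Returns exactly 10 named surfaces in healthy mode and 6 in light-damage
    mode; in the latter the ONL-Top and BM surfaces may coincide column-wise
    (zero minimum separation).
    """
    work = downsample_volume(volume, lateral_factor, axial_factor)
    if plan is None:
        plan = build_plan(mode, work.spacing[2])
    if plan.mode != mode:
        raise ValueError(f"plan is for mode {plan.mode!r}, not {mode!r}")
    roi = coarse_localize(work)
    needs_features = models is not None and any(
        m != "gradient" for m in (models.values() if isinstance(models, dict) else models))
    stack = costs_mod.extract_features(work, roi) if needs_features else None

    B, X = work.shape[0], work.shape[1]
    floor = np.clip(np.floor(roi.ilm).astype(int), 0, roi.z1) - roi.z0
    ceil = np.clip(np.ceil(roi.deep).astype(int), 0, roi.z1) - roi.z0
    floor = np.clip(floor, 0, roi.depth - 1)
    ceil = np.clip(ceil, 0, roi.depth - 1)

    surfaces: dict[str, np.ndarray] = {}
    prev_low = None
    for k, stage in enumerate(plan.stages):
        if models is None:
            model = "gradient"
        elif isinstance(models, dict):
            if k not in models:
                raise ValueError(f"no model provided for stage {k}")
            model = models[k]
        else:
            model = models[k]
        if model != "gradient" and (model.mode != mode or model.stage != k):
            raise ValueError(
                f"stage/model mismatch: model (mode={model.mode}, stage={model.stage}) "
                f"given for mode={mode}, stage={k}")
        cvs = _stage_costs(work, stack, model, stage, roi)
        stage_floor = floor if prev_low is None else np.maximum(
            floor, prev_low - GUARD_VOXELS)
        t0 = time.time()
        pos = segment_surfaces(cvs, stage.constraints,
                               column_floor=stage_floor, column_ceil=ceil)
        logger.info("stage %d (%s): solved in %.1fs", k + 1,
                    "/".join(stage.surfaces), time.time() - t0)
        for i, name in enumerate(stage.surfaces):
            surfaces[name] = (pos[i] + roi.z0).astype(float)
        prev_low = pos[-1]  # window-local lowest surface of this stage
        if mode == "ld" and "ONL-Top" in stage.surfaces and model != "gradient":
            # visibility rule: where the classifier finds no ONL-Top evidence
            # anywhere in the column (the residual outer band has vanished),
            # the top of the ONL collapses onto Bruch's membrane
            k_on = stage.surfaces.index("ONL-Top")
            p_max = 1.0 - np.min(cvs[k_on], axis=2)
            # visibility is a regional property: median-filter the per-column
            # evidence so vessel shadows (narrow lateral stripes of spurious
            # or suppressed probability) follow their surroundings
            p_med = ndimage.median_filter(p_max, size=(3, 9), mode="nearest")
            invisible = p_med < ONL_VISIBILITY_P
            surfaces["ONL-Top"] = np.where(invisible, surfaces["BM"],
                                           surfaces["ONL-Top"])

    # a guard band allows up to GUARD_VOXELS of cross-stage overlap; restore
    # monotonicity by a cumulative max in anatomical order
    order = [n for n in SURFACE_ORDER[mode]]
    arr = np.stack([surfaces[n] for n in order])
    arr = np.maximum.accumulate(arr, axis=0)
    work_set = SurfaceSet({n: arr[i] for i, n in enumerate(order)}, "downsampled")
    out = rescale_surfaces(work_set, lateral_factor, axial_factor,
                           native_x=volume.shape[1])
    out.check_ordering()
    return out


def train_stage_models(volume: OCTVolume, delineations: list[Delineation],
                       mode: str, seed: int, plan: StagePlan | None = None,
                       lateral_factor: int = 2, axial_factor: int = 2) -> dict:
    """Train one boundary classifier per stage from sparse native-resolution
    delineations of ``volume`` (e.g. simulated-rater tracings).

    The volume is downsampled to the working grid, delineation coordinates
    are scaled accordingly, and each stage's multiclass random forest is
    trained on the slices that trace all of that stage's surfaces.
    """
    work = downsample_volume(volume, lateral_factor, axial_factor)
    if plan is None:
        plan = build_plan(mode, work.spacing[2])
    roi = coarse_localize(work)
    stack = costs_mod.extract_features(work, roi)
    scaled = [
        Delineation(
            rater=d.rater,
            slices=[{"b": r["b"], "surface": r["surface"],
                     "points": (np.asarray(r["points"], float)
                                / [lateral_factor, axial_factor]).tolist()}
                    for r in d.slices],
            rule=d.rule, repeat=d.repeat)
        for d in delineations
    ]
    models = {}
    for k, stage in enumerate(plan.stages):
        models[k] = costs_mod.train_boundary_classifier(
            stack, scaled, stage=k, stage_surfaces=stage.surfaces,
            mode=mode, seed=seed + k)
    return models
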