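# Methods

This note documents the models, algorithms and numerical choices behind
`octlayers`, and what the synthetic test bed does and does not establish.

## Coordinate and unit conventions

Volumes are indexed `(b, x, z)` — B-scan, A-scan, depth — 0-based, with
`z = 0` on the vitreous side. Surface positions are floats in voxel units at
their native resolution; micrometre conversion happens only in the metrics
and statistics layers. The reference acquisition geometry is 1000 A-scans ×
100 B-scans × 2048 depths over 1.4 × 1.4 × 1.6 mm (1.4 µm lateral, 0.78 µm
axial); the desk-scale phantom default (25 × 128 × 512 over the same
physical extent) keeps the axial voxel size and shrinks the lateral grid.

## Exact multi-surface optimisation

`segment_surfaces` finds the exact global minimiser of the summed per-column
boundary cost over all surfaces of a stage, subject to hard smoothness
bounds (|Δz| per adjacent column) and pairwise min/max separations. The
feasible set is a lattice and the objective is modular, so the optimum set
is closed under pointwise minimum; the solver returns that pointwise-minimal
optimum (computed as the source-minimal minimum cut, i.e. the
residual-reachable side of a max flow), which makes results deterministic:
ties break toward smaller z, then toward the earlier surface. A brute-force
oracle (exhaustive enumeration, same tie-break via the meet of all optima)
cross-checks the solver on hundreds of random small instances in the test
suite.

Graph construction is the standard closure ("project selection") scheme:
one node per (surface, column, z) with transformed weight
`w(z) = c(z) − c(z−1)`; infinite arcs encode downward closure, smoothness
(`(s,i,z) → (s,j,z−Δ)`, clamped at the base) and separations; the base row
carries `c(z₀) − L` with `L` large enough that every base node joins any
minimal closure. Per-surface z-ranges implied by the separation constraints
are propagated to a fixed point first; an empty range raises before any
graph is built.

**Fixed-point capacities.** The max-flow kernel
(`scipy.sparse.csgraph.maximum_flow`) operates on 32-bit integer
capacities — larger integer inputs are silently truncated, which we guard
against explicitly. Integer costs whose derived capacities fit 32 bits are
solved exactly. Float costs are normalised to [−1, 1] (a global positive
scaling never changes the optimiser) and quantised at the largest power-like
scale whose capacities — including `L` — stay inside 2³¹, verified in
integer arithmetic; for the pipeline's probability costs the resolution is
≈10⁻⁴ of the cost range or finer, far below any meaningful probability
difference.

**Region-of-interest bounds.** Per-column floors/ceilings (the coarse ROI
and the stage-to-stage restriction) are imposed as a finite penalty of 8×
the normalised cost range per violating column, not as hard node removal.
Whenever a penalty-free feasible configuration exists — which the stage
plans guarantee by construction — the optimum never pays a penalty, and the
uniform node budget keeps the graph construction vectorised and the 32-bit
capacity budget predictable.

## The three-stage pipeline

`segment_retina` downsamples 2× laterally and axially (B-scan count
unchanged), then:

1. **Coarse localisation** — a further 4× downsample, gradient costs
   (dark→bright for the ILM, bright→dark for a deep outer-retina/choroid
   transition), a 2-surface simultaneous solve, rescale. ROI = [ILM − 20 µm,
   deep + 40 µm] per column; the deep boundary is auxiliary and never
   reported.
2. **Stage 1** ILM + RNFGC-IPL; **Stage 2** IPL-INL, INL-OPL (+ OPL-ONL in
   healthy mode); **Stage 3** ELM, EZ-Top, EZ-Bottom, OS-RPE, BM (healthy)
   or ONL-Top, BM (LD). Each stage is confined at-or-below the previous
   stage's lowest surface minus a 2-voxel guard band; the final stack is
   made monotone by a cumulative max (the guard band permits ≤ 2 voxels of
   overlap).
3. Rescale to native resolution (axial multiplication, lateral linear
   interpolation with edge extension).

Constraint defaults (working-grid voxels): smoothness 2 laterally, 6
between B-scans — deliberately relaxed to absorb axial motion jitter —
and pair separations at the nominal layer gap ± 50 %. All are configuration
(`build_plan`), not claims about any particular instrument; the LD
(ONL-Top, BM) pair has minimum separation 0 so the outer band may vanish.

**Boundary costs.** A multiclass random forest per stage per mode
(100 trees, unlimited depth, out-of-bag score recorded; healthy and LD model
families are disjoint). Features per voxel: raw intensity; Gaussian-smoothed
intensity and signed axial derivative at σ ∈ {1, 2, 4} axial voxels (half
laterally); signed distance to the coarse ILM; relative ROI depth (0 at the
ILM estimate, 1 at the deep estimate, clipped); normalised lateral position.
Training labels: voxels within ±1 axial voxel of a delineated surface take
that surface's class — the nearest surface where bands overlap, with exact
ties split by voxel parity so coincident tracings feed both classes —
and background is subsampled to 2× the mean surface-class count.
Probabilities map to costs as `cost = 1 − P`: bounded and monotone, whereas
−log P would produce infinities. Gradient costs (negated polarity-signed
axial derivative of the smoothed volume, shifted non-negative) remain
available for any stage and suffice on noise-free data.

**Collapse of the vanished outer band.** Two rules mirror how such data is
actually annotated and read. The simulated rater does not trace ONL-Top
where the outer band is thinner than 6 µm (below the practical visibility
of a boundary at this axial resolution), so the classifier learns no
ONL-Top appearance for ablated tissue. After the LD outer stage, ONL-Top is
set equal to BM wherever the column-maximum P(ONL-Top), median-filtered
over 3 B-scans × 9 columns, falls below 0.6: visibility is a regional
property of the tissue, and the median filter keeps narrow vessel shadows
from either faking or destroying it. On pilot phantoms the filtered
statistic is strongly bimodal (≲0.6 in ablated tissue, ≳0.65 where the band
is visible), which fixed the threshold.

## The phantom as study stand-in

The generator emulates: piecewise-layered axial reflectivity (hyperreflective
RNFGC/IPL/OPL/EZ/RPE, hyporeflective INL/ONL — ordering chosen to match
mouse OCT contrast; absolute values are free parameters, as no intensity
statistics are published for the instrument); layer thicknesses defaulting
to the control-group magnitudes of the longitudinal study (RNFGC 12, IPL 39,
INL 25, OPL 12, ONL 53, photoreceptor complex 49 µm — inner retina 76,
outer 114, total 190 µm); a radially symmetric ONH depression with compact
support (fully contained within ~1.15× its 120 µm radius, so the analysis
annulus is untouched) where all surfaces converge toward BM; vessel shadows
(6 columns of width 3, attenuation 0.45) below the RNFGC; common-mode
low-frequency undulation (4 µm) and tilt (6 µm); per-B-scan axial jitter
N(0, 2 voxels); multiplicative gamma speckle (shape 20, emulating 10-frame
averaging by a high shape parameter) plus additive Gaussian noise (σ = 4 on
a 10–170 intensity scale). Rendering uses partial-voxel coverage, so the
noiseless limit is exactly piecewise constant and truth surfaces are exact.
LD mode replaces the photoreceptor stack with a remnant band of
(1 − severity) × 102 µm (default severity 0.75 ≈ the day-6 cohort), thickens
the INL to 32 µm, and can force severity 1.0 in a region (with a 15-px
lateral taper so truth remains within the solver's smoothness bounds).

What the phantom does **not** model: physical OCT point-spread and
depth-dependent attenuation, real vessel geometry (shadows are straight
columns), acquisition frame averaging, eye-specific anatomy, or the
biological mechanism of INL thickening (only its summary statistics).
Passing tests therefore demonstrate the correctness of the optimisation,
learning and analysis machinery under controlled, realistic-magnitude
conditions — not clinical-grade accuracy on real scans.

Simulated raters sample truth every 8 px (configurable) with N(bias, σ²)
axial noise in µm; σ = 1.0 µm reproduces the ~1.1–1.3 µm mean unsigned
intra-/inter-rater differences reported for human raters (the folded-normal
mean of a pairwise difference is 2σ/√π). Cohort simulation draws per-eye
Gaussian thicknesses from a published mean ± SD table (8 layers × 2 groups ×
4 days; the LD ONL cells at days 1 and 3 are absent there and are omitted).

## Validation and statistics conventions

- Evaluation annulus: 0.3 mm inner / 1.2 mm outer diameter, radii computed
  with anisotropic spacing, both boundaries inclusive (a deterministic rule
  where the protocol is silent).
- `border_error` pools |Δz|·spacing over masked columns;
  `variability_tables` aggregates per-slice means as mean ± SD across
  slices (matching per-slice reporting; per-column pooling is available).
  The BM serves as surrogate reference for an untraced ONL-Top.
- Layers: RNFGC (ILM→RNFGC-IPL), IPL, INL, RNFGC+IPL, IR (ILM→INL-OPL),
  ONL (OPL-ONL→ELM healthy; ONL-Top→BM in LD), OR (INL-OPL→BM), TRT
  (ILM→BM). OR's lower bound is BM — the only reading under which
  IR + OR = TRT holds, as the published group means do (76 + 114 ≈ 190).
- Quadrants: the annulus split by the ±45° diagonals, superior at the top
  of the en-face image by default; the orientation is a parameter (rotating
  by 180° swaps S↔I and N↔T exactly), and diagonal ties go to the S/I pair.
- Group comparison: paired t-tests pairing by eye index, α = 0.01, no
  multiple-testing correction (matching the study's analysis); a Welch
  two-sample option exists because the pairing rationale between independent
  groups is unstated. Identical groups return p = 1 with a warning rather
  than a degenerate test.
- Cohort summaries are whole-annulus means; quadrant-resolved simulation is
  supported through an optional `quadrant` column.

## Problem sizes and runtime

Default test-bed volumes are 25 × 128 × 512 (segmented at 25 × 64 × 256);
stage graphs hold 0.5–1 M nodes and solve in seconds each, so a full
train-plus-segment cycle takes well under a minute on one core. The
brute-force oracle is restricted to instances with ≤ 10⁷ raw
configurations. These sizes are the package's chosen desk scale; all
components accept full-resolution volumes unchanged.

## Known limitations

- Exactness for float costs is exact-up-to-quantisation (≈10⁻⁴ of the cost
  range); integer costs are solved exactly.
- ROI confinement is a large-but-finite penalty, not a hard constraint; a
  pathological cost volume could in principle buy its way out of the ROI.
- Surfaces are only rescaled to native resolution after the working-grid
  solve; no full-resolution refinement pass is performed.
- The ONL-Top visibility rule is regional; an isolated visible islet
  narrower than the median-filter window inside ablated tissue would be
  collapsed.
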