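# Methods

This note documents the models, numerical choices and limitations behind
`colonysim`. Everything stated here is exercised by the test suite or the
acceptance script; no empirical claim below goes beyond what those
computations measure.

## Cell geometry

Cell outlines are closed polygonal chains in µm, stored counterclockwise
and validated on construction (≥ 8 vertices, simple, nonzero area). The
catalogue:

- **rod** — capsule: rectangle of length *l − w* capped by two semicircles
  of radius *w*/2. *l* is tip-to-tip, matching how length is read off a
  micrograph. Closed-form area *w(l − w) + π(w/2)²*.
- **bent rod** — the capsule's centerline is a circular arc of arc length
  *l − w* subtending a total angle *β* (the `bend` parameter, radians).
  The arc-angle parametrization was chosen over a curvature radius because
  it is bounded, dimensionless and stable as cells elongate. The offset
  band preserves the straight capsule's area (Pappus), which the tests
  exploit. Validity requires the centerline radius *(l − w)/|β|* to exceed
  the cap radius *w*/2, otherwise the inner offset curve self-intersects;
  the constructors enforce this.
- **coccoid** — circle of diameter *w*; grows isotropically.
- **ellipsoid** — ellipse with semi-axes *l*/2, *w*/2.

The default discretization is 32 vertices per cell: at the default
calibration of 0.09 µm/pixel the chordal error of a 32-gon around a
µm-scale cell is well below one pixel. Inscribed polygons approach the
closed-form area from below; at 64 vertices the error is ≈ 0.1–0.2%.

## Growth and size homeostasis

Elongation is exponential in length, dL/dt = kL — the standard law for
single bacterial cells — so one step of duration Δt multiplies the length
by exp(kΔt). Two phenomenological division rules are implemented:

- **timer**: divide when age ≥ τ;
- **sizer**: divide when length ≥ L_div.

An adder rule is deliberately not implemented. Division is symmetric
fission: daughters take half the mother's length each (an optional split
CV jitters the fraction while conserving total length exactly), are
placed end-to-end on the mother's axis at ±L/4, and get the mother's
angle perturbed by a Gaussian (default σ = 0.05 rad) — enough to produce
the fan-out of real monolayer colonies while keeping σ = 0 exactly
conservative for tests. Rates and triggers are drawn from lognormal
distributions parametrized by arithmetic mean and CV (positive support;
CV = 0 degenerates to the exact mean).

Numerical choice: trigger comparisons use a 10⁻¹² *relative* slack.
Floating-point products such as (2^{1/m})^m land a few ulp below their
exact value, and a strict ≥ would then postpone a division by one full
step, breaking the closed-form cv=0 trajectories (2ⁿ synchronous counts,
birth lengths exactly L_div/2). The slack is ~10⁴ times smaller than any
physically meaningful length or time difference.

Fluorescence is an emission density per unit area; daughters inherit the
mother's density, so total colony emission is conserved through division.

## Simulation loop

Each step runs in fixed order: grow all cells by Δt → divide every cell
whose rule fires (ascending id; new daughters are not re-examined within
the step) → resolve overlaps → advance the clock. Default Δt is 1 min
(1/60 h), a typical time-lapse cadence. Founders start at the sizer
steady-state birth length (trigger/2; 1.5 µm default for timer) scattered
in a small disc. Reproducibility: founder parameters come from a
generator seeded from the run seed, and each division uses a generator
keyed on (seed, step, mother id), so trajectories are bit-identical for a
fixed configuration and independent of iteration order.

## Overlap resolution

The solver treats every shape as a capsule for contact *detection*: a
centerline polyline plus radius (rod: segment; coccoid: point; ellipsoid:
capsule over-approximation; bent rod: arc sampled finely enough that the
chordal error is negligible against the depth tolerance). Penetration
depth of a pair is r_i + r_j − dist(spine_i, spine_j) with segment–segment
distances computed vectorized over all candidate pairs (k-d-tree
bounding-circle broad phase). Each relaxation pass pushes both cells apart
along the contact normal by half the damped depth and applies a torque
from the off-axis contact point (normalized by an area-based radius of
gyration), which reorients rods tangentially — the origin of the nematic
ordering in dense rod colonies.

Convergence is *judged* on the exact polygons: an outer iteration
intersects all candidate polygon pairs (STR-tree + exact polygon
intersection) and stops when every overlap is ≤ `overlap_tolerance`
(default 1%, sub-pixel at 0.09 µm/pixel) of the smaller cell's area. If a
relaxation round would increase the global overlap area it is reverted
and retried with halved steps; a radial expansion about the colony
centroid is the fallback for uniformly compressed packings. The logged
per-iteration totals are therefore non-increasing by construction. The
depth tolerance starts at 0.35 · tolerance · min width and is halved
whenever the spine model and the polygon oracle disagree, so capsule
approximation error cannot leave the contract unsatisfied.

The colony is strictly 2D (monolayer assumption): no out-of-plane escape
under crowding. An optional rectangular arena clamps cells inside.

## Rendering

Stages, in fixed order, all parameters exposed:

1. **Ideal raster** — background 0.7, cell interior 0.25 (dark cells on a
   bright field; declared defaults, not measurements). The polygon→pixel
   map places pixel (r, c) over [c·s, (c+1)·s) × [r·s, (r+1)·s) µm with
   s the calibration, camera centred on the colony centroid. Boundary
   pixels take area-weighted values via 4× supersampling, so the
   integrated intensity deficit equals the colony area to ≈ 0.1%.
2. **Halo** — difference-of-Gaussians composite on d = image − background:
   out = bg + w₁·G(σ₁)∗d − w₂·G(σ₂)∗d, defaults σ₁ = 1 px, σ₂ = 6 px,
   w₁ = 1.0, w₂ = 0.4, chosen so line profiles through a cell show a dark
   interior and a bright rim just outside the edge. Constant images pass
   through unchanged.
3. **Uneven illumination** — multiply by 1 + a·f with mean(f) = 0 and
   max|f| = 1; f is a random 2nd-order polynomial surface by default
   (typical flat-field error), or broadly blurred noise with correlation
   length `illumination_scale`.
4. **Noise** — out = clip(img·(1 + ε_m) + ε_a), ε per pixel Gaussian.
5. **Quantization** — 8 or 16 bit.

Fluorescence: per-cell uniform emission rasterized then convolved with a
Gaussian PSF (flux conserved away from borders, verified to 2%); optional
Poisson shot noise at 10⁴ photons per intensity unit. Fluorescence and
phase contrast draw independent noise.

`histogram_correlation` (Pearson correlation of intensity histograms over
a common range) is the realism QC; frames rendered from one configuration
with different noise seeds correlate > 0.99.

## Ground-truth emitters

Annotations use the renderer's exact camera transform, so masks and boxes
align with frames to sub-pixel accuracy. Conventions: COCO uses polygon
segmentation (not RLE), category 1 "cell", bbox [x, y, w, h]; YOLO writes
class-first normalized boxes, one file per frame; label masks are 16-bit,
labels 1..n in ascending cell id, residual overlap pixels assigned to the
smaller id (deterministic); TrackMate XML is a minimal
Model/AllSpots/AllTracks skeleton with one spot per cell per frame
(µm positions, equivalent-area radius) and edges for frame-to-frame
continuations and mother→daughter links. Meshes are surfaces of
revolution (capsule, sphere, revolved ellipse; the bent rod is a capsule
mesh bent along its arc), watertight by construction, with volumes within
1% of closed forms at the default angular resolution of 64.

## Dataset generator

The batch generator emulates a training-set workflow: `n_images`
*independent* colonies (one simulation per image, seeded from the dataset
seed + image index, stated in the manifest), each snapshotted once its
cell count reaches a per-image target drawn log-uniformly over the
configured range — a density spread that favours the small/medium frames
detector training benefits from while still covering dense colonies. When
the range starts at 0 the log-uniform draw naturally yields occasional
empty frames. Colony growth uses Δt = 0.1 h for speed; if a coarse step
would overshoot the admissible count range the generator re-advances from
the previous state at Δt/20. The reference configuration (128 images,
512 × 512 px, 0.09 µm/pixel, counts 0–512) regenerates in a few minutes
on one CPU and is bit-identical across runs.

## What the generator does and does not emulate

Synthetic frames reproduce the *statistics* real training pipelines care
about — cell/background contrast, halo rims, smooth illumination bias,
sensor-like noise, realistic packing geometry — with exactly known ground
truth. They do not model physical phase-contrast optics (Zernike ring,
wave propagation), camera fixed-pattern noise, focus drift, debris, or
biological heterogeneity beyond the lognormal rate/trigger spread (no
death, lysis, motility, or nutrient coupling). Passing tests therefore
demonstrate internal consistency and statistical realism of the stated
noise model, not photorealism; bridging the remaining gap is what
GAN-style refinement or domain adaptation would add downstream.

## Test problem sizes

The suite runs desk-scale problems chosen to keep closed forms exact and
oracles cheap: 32–256-cell colonies for growth/packing checks, 512² flat
frames for noise moments, 8–12-image datasets for determinism and
reference-configuration checks (the acceptance script runs the full
128-image configuration). Monte-Carlo oracles use 10⁵ points at fixed
seeds.
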