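# Methods

## Shape model

Each axial prostate cross-section is modeled as a deformable
superellipse. The centered shape is given parametrically by
`x = ax·|cos θ|^(2/ε)·sign(cos θ)`, `y = ay·|sin θ|^(2/ε)·sign(sin θ)`
and implicitly by the inside–outside function
`f(x, y) = |x/ax|^ε + |y/ay|^ε` (1 on the boundary, <1 inside). The two
forms are algebraically consistent (`|x/ax|^ε = |cos θ|²`), which the
test suite verifies to 1e-9 over random parameters.

Four deformations compose in a fixed order — rotation by `r`, linear
tapering `x′ = (t·y/ay + 1)·x`, circular bending
`x′ = x + (1 − √(1 − (b·y)²))/b`, translation by `(lx, ly)` — and each is
closed-form invertible, so points can be mapped between the image frame
and the centered frame exactly. Invariants `ax, ay, ε > 0`, `|t| < 1`
and `|b|·ay < 1` keep the composite map injective over the shape;
parameter vectors violating them are rejected, and the optimizer's box
bounds (`ε ∈ [0.6, 4]`, `|t| ≤ 0.6`, `|b|·ay ≤ 0.5`) keep fitted shapes
inside the prostate-plausible subset. A 3D superellipsoid is deliberately
not used: a single global 3D primitive is too rigid for real glands,
whereas a per-slice model with interpolated parameters can follow
base-to-apex shape change.

### Parameters that matter

| parameter | units | meaning | typical prostate range |
|---|---|---|---|
| ax, ay | mm | semi-axes | 8–25 |
| lx, ly | mm | center | — |
| r | rad | in-plane rotation, CCW | ±π/2 |
| ε | – | squareness (2 = ellipse) | 1.5–3 |
| t | – | taper of x-extent along y | ±0.2 |
| b | 1/mm | curvature of posterior bend | 0–0.01 |

## Rasterization

Masks are produced by forward mapping: lattice points of the centered
frame satisfying `f ≤ 1` (lattice supersampled 8× per pixel axis) are
pushed through the deformations and binned onto the pixel grid; a pixel
becomes foreground when its estimated coverage reaches half the pixel
area. Each point is weighted by the local area Jacobian of the
deformation (only tapering changes area; rotation, bending and
translation are area-preserving), so coverage is unbiased where the map
expands or shrinks. For a locally straight boundary the half-coverage
rule coincides with center-inside thresholding, and the suite checks
Dice ≥ 0.99 against an independent inverse-map rasterizer on random
shapes. Morphological closing (3×3 square, up to 5 passes) then a hole
fill guarantee a single, hole-free component even for extreme parameter
combinations the optimizer may probe.

## Slice fitting

The fit maximizes the posterior over `p`: minimize
`E(C; U) = Σ_u d(C, u)²` (squared point-to-boundary distance; a flag
switches to plain distances) minus `w·ln Pr(p_s)` when the Gaussian shape
prior is enabled. The prior is implemented but off by default — no
published hyperparameters `m_j, σ_j` exist for it, and inventing them
would bias fits; the box bounds act as the uniform pose prior.

During optimization the contour `C` is the analytically deformed
parametric boundary (120-gon), not the rasterized mask boundary. The two
describe the same curve (rasterization only samples it), but the
polygon's point distances vary smoothly with `p`, whereas a rasterized,
morphologically closed mask makes the energy piecewise constant on the
pixel scale and an order of magnitude slower per evaluation. With the
analytic contour a bounded Nelder–Mead simplex (4 deterministic
multistarts; initialization at the click centroid, principal-axis
rotation, max-extent semi-axes, ε = 2, t = b = 0; custom initial simplex
steps so mm-scaled and dimensionless parameters explore at comparable
rates) recovers all eight parameters from 12 noiseless points to Dice
> 0.998 in ~0.5 s. The returned energy never exceeds the energy at the
initialization, and results are deterministic given the config seed.

B-spline mode (recommended for irregular mid-gland slices with ≥ 6,
ideally 10–12 points): clicks are sorted angularly about their centroid,
a closed periodic smoothing spline (`scipy.interpolate.splprep`) is
sampled at ≥ 200 points, and the superellipse is fitted to those samples
so the 3D model stays parametric. The second user iteration — editing
exported contour points — re-enters through the same pathway.

## 3D reconstruction

At least three annotated slices (base, mid-gland, apex) anchor a stack of
`(z, p)` entries. Every plane in between gets `p` by component-wise
linear interpolation; rotation interpolates along the shortest circular
arc to avoid the ±π seam. The model spans exactly the annotated z range —
no extrapolated capping beyond the extreme slices, since any cap shape
would be an invention; a gland annotated to its true extremes loses at
most half a slice thickness per end. Contour export samples each model
slice at equal arc length (default 12 points) for the refinement
iteration.

## Registration

Segmentation-based: both masks are cropped to their bounding box plus a
10 mm margin, resampled to 0.3 mm isotropic voxels (nearest neighbor, so
masks stay binary; the origin shifts by half the spacing change to keep
voxel-edge extents aligned), smoothed with a σ = 3 voxel Gaussian
(interpreted in voxels of the isotropic grid, i.e. 0.9 mm physical,
following the pipeline order), re-thresholded at 0.5 (the signed
transform needs a binary input; 0.5 keeps the surface unbiased) and
converted to a signed Euclidean distance map. The map assigns every
voxel its exact distance in mm to the nearest boundary voxel (foreground
voxels with a 6-connected background neighbor), negative inside — an
exact Euclidean distance transform; the suite cross-checks it against
ITK's signed Maurer filter and against brute-force boundary distances
(the latter to 1e-6).

Distance maps share an intensity scale across modalities, so SSD is the
dissimilarity. Optimization is SimpleITK's regular-step gradient descent
(learning rate 1.0, min step 1e-4, ≤ 200 iterations, multi-resolution
shrink 4/2/1), a rigid stage initialized from either the image centers
(identity rotation about the moving image's center, translation between
centers) or a closed-form least-squares rigid landmark fit (orthogonal
Procrustes on ≥ 3 non-collinear matched fiducials), then a full affine
stage. The metric during optimization is evaluated on a seeded random 5%
voxel sample — distance maps are smooth, so sparse sampling changes the
optimum negligibly while cutting runtime ~10× — and the reported
initial/final metrics always use every voxel. If a stage ends with a
worse full-volume metric than its start, its result is discarded
(best-so-far semantics), so the final metric never exceeds the initial
one. The fixed image is the MRI-derived map and the moving image the
TRUS-derived one by convention; `--swap-roles` flips this.

## Metrics

Dice, Jaccard, VOE = 1 − Jaccard, and signed RVD = (|P| − |G|)/|G|
(negative ⇒ under-segmentation) are voxel-count ratios. HD and ASSD are
computed between boundary-voxel centers (6-connectivity boundary) in
physical mm via KD-trees; HD is the full 100th-percentile Hausdorff, not
HD95, and ASSD averages both directed distance sets. Voxel-center
distances slightly understate mesh-based surface distances (by up to
half a voxel diagonal), which matters only when comparing against tools
using marching-cubes surfaces.

## Synthetic phantom and annotator

The default phantom is a five-entry stack spanning 40 mm: semi-axes grow
from apex (12×10 mm) to mid-gland (22×18 mm) and shrink to base, with
tapering up to t = 0.2 and posterior bending up to b = 0.01 /mm at
mid-gland — a tapered, posteriorly indented gland of ≈ 36 mL on a
128×128 grid at 0.5 mm in-plane and 2 mm slice spacing (TRUS-like
anisotropy). The simulated annotator picks the two extreme slices and
the largest mid-gland slice, samples 4/10/4 points at equal arc length
with a random phase, and jitters them with isotropic Gaussian noise of
σ = 1 mm (a plausible click error at TRUS resolution; the suite verifies
the realized RMS point-to-contour distance is 1.0 ± 0.1 mm). Registration
pairs resample the phantom under a known affine perturbation onto a grid
with different spacing and origin, emulating MRI/TRUS geometry
differences.

What the phantom does *not* emulate: speckle, shadowing, boundary
dropout, non-superellipse cross-sections, and human click bias toward
visible edges. Passing tests therefore demonstrate the geometric and
numerical correctness of every stage and the identifiability of the model
from sparse noisy points — not clinical segmentation accuracy, which
depends on how well a human places points on real images.

## Problem sizes and numerical choices

Tests and the acceptance script run at the phantom scale above:
128² slice grids (160² for 2D fit checks), 21-slice volumes,
registration volumes of ~200³ voxels after 0.3 mm resampling (a reduced
96² phantom for registration unit tests). Tie-breaks and tolerances:
interpolation treats a z within 1e-12 of an annotated slice as exact;
rasterization counts exactly-half coverage as foreground; angular sorting
of spline clicks breaks ties by radius; degenerate inputs (empty masks,
collinear or duplicate points, < 4 clicks, singular transforms,
out-of-range z) raise `ValueError` with a message naming the offending
quantity.

## Known limitations

- Non-affine residual deformation (probe pressure differences between
  MRI and TRUS sessions) is not modeled; registration is affine only.
- The per-slice model cannot represent cross-sections that are not
  star-shaped about the fitted center (the B-spline pathway mitigates
  in-plane, but the 3D model inherits the superellipse).
- Axial coverage ends at the extreme annotated slices.
- The Gaussian shape prior ships disabled; enabling it requires
  population statistics for `m_j, σ_j` from the deployment site.
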