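# Methods

This note documents the models implemented in `cardioshape`, the numerical
choices behind them, what the synthetic data generator does and does not
emulate, and the problem sizes used by the validation studies.

## Shape model

**Alignment.** Generalized Procrustes analysis iterates: fit each shape to
the current mean with the closed-form similarity solution (SVD of the
cross-covariance, determinant-corrected so reflections are never used; 7
degrees of freedom — scale, rotation, translation), recompute the mean,
re-centre it and rescale it to unit norm. Convergence is declared when the
mean moves by less than 1e-7 (max 100 passes); the summed squared residual
`G` is non-increasing across passes and recorded per iteration. Individual
shapes are not rescaled — only the mean carries the scale constraint.

**Unit convention.** The unit-norm-mean constraint fixes the scale of the
common frame, so aligned coordinates (and hence PCA eigenvalues) are
expressed in units of the mean's norm, not millimetres. To compare recovered
eigenvalues with variances planted in mm, multiply by the squared norm of the
centred template (`TrainingSet.template_scale`); the validation studies do
exactly this. This is a unit conversion, not a correction.

**PCA.** Sample covariance with the N−1 divisor, computed via thin SVD of
the centred data matrix. Eigenvector sign is fixed by making each mode's
largest-magnitude component positive, which removes backend-dependent sign
flips. The default mode count is 50, clamped (with a warning) to the
available rank `min(3n, N−1)`; a cumulative-variance-fraction policy is
available instead. Shape parameters can be clamped to ±3√λⱼ, the
conventional plausibility limit for a Gaussian mode.

## GA meanshape

A deliberately conventional real-coded GA: tournament selection (size 3),
BLX-α crossover (α = 0.5, rate 0.9), per-gene Gaussian mutation (rate 0.15,
σ = 0.08 of the bound width), elitism (1), fixed seed. Candidates with
non-finite fitness are rejected with a warning. The three meanshape
strategies differ only in chromosome granularity — shape parameters `b`
(bounded by ±3√λ), the full 3n coordinate vector (refused above 200 points,
where the chromosome grows impractical), or one 3-gene GA per landmark with
per-shape weights (default uniform; the weights are exposed in the config
since no principled default exists). Every population is seeded with the
objective's analytic optimum (b = 0, the coordinate-wise mean, or the
weighted centroid), so an elitist run can never underperform the trivial
estimator; the GA's role is search, the seed is the safety net. Strategy 3
logs one history per landmark, back to back, in the shared history file.

## B-spline surfaces

Uniform (unclamped) knots everywhere; orders 1–3 supported, cubic by
default. Each span evaluates in matrix form `T M V Mᵀ Wᵀ` with the local
parameters mapped to the unit square, so `M V Mᵀ` is directly the span's
monomial coefficient grid — the representation the exact volume integral
needs. Evaluation agrees with Cox–de Boor recursion to 1e-10 (tested against
an independent scipy implementation).

**Closure.** The circumferential direction wraps periodically, stored as
`order_u` duplicated trailing control slices. Apex and base close by
repeating a single pole point in the first/last `order_v` control slices:
with a uniform degree-k basis the end-span boundary weight of the (k+1)-th
local control point is zero, so the boundary curve degenerates exactly to
the pole and the surface is watertight with sphere topology. This keeps one
basis matrix valid for every span; the degenerate pole patches integrate
through the same formula (their Jacobian vanishes smoothly).

**Fitting.** Landmark grids get uniform parameters (columns → u, periodic;
rows → v, offset inside (0,1) to leave room for the pole caps); the control
net is solved coordinate-wise by linear least squares. Underdetermined or
rank-deficient systems are refused rather than regularized — the default net
size (one control column per landmark column, two fewer interior slices than
landmark rows) keeps the system overdetermined. The RMS residual is stored
on the surface.

**Tessellation** samples span-aligned parameters (the requested resolution is
rounded up to a span multiple) so knot lines — where low-order surfaces are
only C0 — are hit exactly; otherwise a bilinear "cube" would be tessellated
with chamfered edges. Pole rings collapse to fan apices; meshes are
re-oriented outward via the signed volume.

## Volumetry

**Exact.** The enclosed volume equals the flux of F = (0, y, 0) through the
closed surface. Per patch the integrand
`Y·(∂X/∂t·∂Z/∂w − ∂X/∂w·∂Z/∂t)` is a polynomial obtained by coefficient-array
convolution, and its unit-square integral is `Σ C(r,l)/((r+1)(l+1))`. The
signed per-patch contributions are reported; the volume is the absolute
signed total, so orientation only flips the sign. A `paper_dialect` switch
drops the second Jacobian term — the abridged single-term form found in some
derivations, exact only when the cross term integrates to zero (it does for
the cube fixture; the two-term form is the default because correctness must
not depend on the parameterization).

**Simpson.** Composite Simpson integration of cross-section areas along the
longest bounding-box axis of a fine tessellation. Sections are computed by a
self-contained slicer: each straddling triangle contributes one segment
oriented by `ẑ × n̂`, and the shoelace sum over the (closed) loops gives the
signed area without polygon assembly. Vertices exactly on the slicing plane
are treated as ε-above so loops never open; the two end planes are evaluated
1e-8 of the range inside the bounds, where sectioning through a boundary
vertex ring would degenerate.

**Monte Carlo.** Rejection sampling in the bounding box with a z-ray-parity
inside test (vectorized over triangles), binomial standard error, fully
deterministic per seed. Used as the model-free oracle; the consistency study
tessellates at 96×96 so discretization bias stays well below the Monte-Carlo
standard error at 1e5 samples.

## Model-to-image fitting

Profiles are first-derivative (gradient) intensity profiles sampled by
trilinear interpolation at one-voxel steps along the outward grid normal,
normalized by their absolute sum — the standard active-shape-model feature.
Per landmark, the training images give a mean profile of length 2k+1 and a
covariance regularized by a relative ridge (1e-3 of the mean diagonal plus
1e-8), inverted once. Matching minimizes the Mahalanobis distance over
offsets ±(m−k); ties break deterministically toward the smaller absolute
offset. Defaults k = 5, m = 8 (k = 4 in the phantom studies, where the wall
is ~4 voxels thick); both are exposed in the config.

The pose/shape update alternates the closed-form similarity fit with the
linear projection of `b` (clamped at 3σ), a coordinate descent whose
residual is non-increasing; on exact model instances it recovers pose and
parameters to machine precision. The outer loop alternates profile search
and update until the mean landmark move drops below 0.1 voxel (max 50
iterations). Because the candidate set is re-estimated from the image every
pass, the match residual is monotone only up to that re-estimation noise
(observed fluctuations are ≲0.3% near convergence); the full history is
reported, and three consecutive rises trigger a divergence guard that stops
with `converged=False` rather than hiding the failure.

Initialization is moment-based: translation from the centroid of above-Otsu
intensity mass, scale from the ratio of RMS radii, identity rotation. This
is a coarse stand-in for anatomical-knowledge placement of the heart in the
chest, which is qualitative and not computable from the image alone.

## Synthetic data generator

The phantom family is a truncated prolate ellipsoid closed by a flat basal
cap — the classic idealized ventricle, chosen because its cavity volume is
available in closed form (`π a b c (τ − τ³/3 + 2/3)`, truncation fraction
τ = 0.5). Defaults: 70 mm long axis, 25 mm transverse semi-axes, 10 mm wall,
16×12 landmark grid. The epicardium offsets each semi-axis by the wall
thickness, which keeps the surfaces strictly nested (minimum separation
≥ 0.9 wall thickness at the default eccentricity).

Shape variability is planted as three named linear displacement fields —
long-axis stretch, circumferential bulge, apical twist — orthonormalized
against the similarity-transform tangent space (translations, rotations,
isotropic scaling) before use. Without that projection, Procrustes alignment
would absorb part of the planted variance and mode recovery would be
ill-posed; with it, recovered eigenvalues match planted variances to within
sampling error. Mode amplitudes are in mm (the fields are unit vectors in
R³ⁿ); recorded long-axis "gains" make the stretch mode's effect on the
apex-base extent exactly linear in the amplitude.

Image rendering voxelizes the watertight endo/epi grid meshes by column-ray
parity (with a sub-micrometre deterministic jitter so rays never graze mesh
edges) into three intensity classes — blood pool 210, myocardium 100,
background 55 — followed by Gaussian blur (1 mm) and additive Gaussian noise
(σ = 5). The contrasts mimic cine bSSFP MR, where the blood–myocardium edge
dominates the epicardial one; that ordering is what lets gradient-profile
matching lock onto the endocardium. The generator does **not** emulate
scanner physics, anisotropic voxels, papillary muscles, trabeculation,
through-plane motion, or inter-observer landmarking noise — so passing tests
demonstrate the correctness of the algorithms, not clinical-grade robustness.

Cardiac cycles scale the transverse radii by `1 − A sin²(πt/T)` over a
1000 ms cycle. Volume scales with the transverse radii squared, so
`A = 1 − √(1 − EF)` prescribes the ejection fraction exactly; with an even
phase count the samples include true end-diastole and end-systole. The
default contraction amplitude 0.3 corresponds to EF ≈ 0.51, a normal value.

## Validation problem sizes

The studies behind `tests/test_acceptance.py` and `scripts/acceptance.py`
use: 500 shapes for PCA recovery (planted variances 4/1/0.25 mm², random
poses on); 20 pose/shape round trips; 20 full image fits at 44³ voxels
(≈2.6 mm isotropic) with 4 training renderings, init perturbed by 5 mm and
5°; five random phantom surfaces for the three-method volume consistency
(Simpson at 128 slices, Monte Carlo at 1e5 samples); sphere nets of
12/16/20/24 control points for the refinement study; 10-point, 5-shape sets
for the GA optimality gaps; and a 4-phase EF = 0.5 cycle. These sizes give
sampling error comfortably inside every asserted tolerance while keeping the
whole suite runnable in minutes on one CPU.

## Known limitations

- Only similarity (not affine or nonrigid) pose; no multi-resolution image
  pyramid, so the capture range is the profile search length.
- Uniform knots only; no NURBS weights or adaptive knot insertion.
- The Simpson method requires a well-defined long axis and, like any slicing
  scheme, inherits tessellation error; the exact method is preferred and the
  numerical ones are cross-checks.
- Strategy 2 of the GA is intentionally refused for dense grids; it exists
  for small shapes and as a reference point for strategy 3.
- The landmark CSV format stores full double precision in text; files are
  bit-exact round trips but not compact.
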