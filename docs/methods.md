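# Methods

This package maps short-range fiber connectivity density (SFiCD) over a
cortical surface and tests it across subjects. It is organized as five
stages — phantom generation, deterministic tractography, cortical-unit
parcellation, density mapping, and vertexwise statistics — each usable on
its own from Python, with a thin CLI tying them into one reproducible run.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## Tractography

The tracker is a FACT-style deterministic streamline integrator over a
field of per-voxel fractional anisotropy (FA) and unit principal
directions. From each seed it propagates bidirectionally: at every step the
nearest voxel's direction is sign-aligned to the incoming direction
(diffusion is axial, so stored signs are meaningless and the phantom
deliberately randomizes them), rejected if the unblended turn exceeds the
angle threshold, blended with the previous step direction by a momentum
factor, and the position is advanced one step. Propagation stops on low FA
at the new point, a sharp turn, grid exit, or a safety cap; the violating
point is discarded, and the two half-tracks share the seed point once.

Defaults: FA threshold 0.14, turning angle 35°, step 0.5 mm, momentum 0.5,
one seed per voxel center, and an inclusive 10–65 mm length window for the
short-range selection. The step is read as millimetres (half the in-plane
pitch of typical 2 mm diffusion data); "smoothing 0.5" is the fraction of
the previous direction retained in the blend. FA is sampled at the nearest
voxel by default (trilinear optional); directions are always
nearest-voxel, which keeps the analytic oracles exact. The angle test uses
the raw voxel direction rather than the blended one because momentum would
otherwise mask sharp turns. Seeding is volume-wide over supra-threshold
voxels; no anatomical mask is assumed.

Two discretization effects bound the accuracy seen in tests. First,
explicit Euler chord-stepping on a curved path drifts outward by
step²/2R per step, about 0.8 mm over a full semicircle of radius 5 mm at
0.5 mm steps. Second, seeds sit anywhere inside a tube of radius r around
the true trajectory, so recovered lengths on an arc spread by roughly
±r/R of the arc length. Recovery on curved bundles is therefore asserted
on the median of the length-filtered tracks (fragments below 10 mm are
exactly the "false tracts" the short-range window exists to remove), and
the curved-geometry tests disable momentum, whose lag otherwise pushes
trajectories out of thin tubes — that test isolates stepping geometry, not
the blend.

## Phantoms

Bundles are circular-arc tubes defined by their endpoints and sagitta
(arc depth), which gives a closed-form arc length
2R·asin(c/2R) (supplement of the half-angle for major arcs), with
R = (c²/4 + s²)/2s — so every tracking claim can be checked against an
analytic number. Voxels within the tube radius of the arc carry the
bundle FA and the local tangent; everywhere else carries background FA and
a random unit direction. FA noise is additive Gaussian clipped to [0, 1];
direction noise is a random-axis rotation of stated angular SD, which
preserves unit norm exactly. Overlapping tubes resolve to the nearest arc.

The synthetic cohort generator emulates the statistics stage's inputs
directly: per-subject vertexwise maps equal to a baseline map plus a group
offset map, a group × moderator interaction map, a per-month rate map
times follow-up, and spatially smooth noise (white noise passed through
the package's own geodesic smoother, then rescaled so the realized SD
equals `noise_sd`). Covariates default to an older-adult cohort — age
≈ 74 ± 3.5 y, education ≈ 5 y, intracranial volume ≈ 1.46 × 10⁶ mm³,
log-normal homocysteine with median ≈ 17 µmol/L, 27-month follow-up,
20 subjects per group — with homocysteine median-split recorded in the
design table. What these phantoms do **not** emulate: gyrified geometry,
registration error between subjects, spatially varying noise,
non-Gaussian tails, or any coupling between covariates and maps. Passing
tests therefore establish the correctness and calibration of the
machinery, not robustness to real-brain confounds.

## Parcellation and voxel layers

The gray–white interface mesh is tiled into K contiguous cortical units
(CUs; 1000 at brain scale, scaled down with the mesh) by farthest-point
sampling on graph-geodesic distances followed by geodesic Voronoi
labeling. This choice is deterministic given the seed of the first sample,
needs no iterative clustering, and empirically keeps the max/min CU area
ratio under 3 on a sphere at K = 100. Distances are graph geodesics, not
polyhedral geodesics; at patch scale the error is bounded and irrelevant
to contiguity. Ties in farthest-point selection are rounded away (1e-8)
so rigid motion of the mesh reproduces the same seed set.

Each CU's subcortical voxel layer is found by sampling along inward vertex
normals to a configurable depth (default 2 mm — one voxel of the coarsest
typical pitch, "layer" being read as singular) at half-voxel spacing. A
voxel claimed by several CUs goes to the CU with the nearest claiming
vertex, ties to the lower CU id, so masks are disjoint and border fibers
are never double-counted. CUs that capture no voxels are flagged and
excluded — never zero-filled, which would conflate "no data" with "no
connectivity".

## SFiCD

For each CU, SFiCD = Σ_f FA_f / V_CU (mm⁻³): the sum of the mean FA of
every short-range fiber terminating in the CU's voxel layer, divided by
the layer volume. Tracking runs once per volume and fibers are assigned to
CUs by their terminal points: a fiber joining two CUs counts in both, a
fiber with both ends in one CU counts once, pass-through is ignored. (The
original formulation tracks per-CU with the mask as a seed region; a
shared tractogram gives equivalent coverage without duplicating fibers at
CU borders and keeps the whole map reproducible from one pass.)
V_CU is the voxel-layer volume, not patch area times a nominal thickness.

Per-CU values are projected as a piecewise-constant vertex map, carried to
a template through an explicit vertex correspondence (identity for
synthetic cohorts; real spherical registration must be supplied — it is
FreeSurfer territory), and smoothed with a geodesic Gaussian kernel,
default FWHM 15 mm, σ = FWHM/√(8 ln 2), truncated at a 2.5σ graph radius
(<1 % mass) and row-renormalized. Within the truncation neighborhood the
kernel uses Euclidean inter-vertex distances rather than summed edge
lengths: lattice inflation of graph distances (~10 %) would otherwise
narrow the effective kernel below nominal, and at kernel scale the surface
is near-flat, so the Euclidean distance tracks the true geodesic closely.
With this choice the measured impulse-response FWHM on a fine flat sheet
is 15.0 mm, and the smoothness estimator (below) is consistent with the
smoother — which is what the Monte Carlo null calibration relies on.
Missing vertices are excluded with weight renormalization and stay
missing.

## Statistics

Group and interaction effects use a "different offset, different slope"
(DODS) design: each group has its own intercept and its own slope per
covariate. Covariates are demeaned across the cohort, so the offset
contrast compares groups at the average covariate value instead of an
extrapolation to zero (undemeaned intracranial volume, ~1.5 × 10⁶ mm³,
would inflate the offset-contrast variance enormously) — this also makes
the contrast t invariant to affine rescaling of covariates. The moderator
(serum homocysteine) is binarized at the pooled median before entering,
ties to the low group; the interaction contrast is the difference of its
per-group slopes. Fitting is ordinary least squares vectorized over
vertices, t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻¹c), two-sided p, df = n − rank(X);
vertices with missing subjects are refit per missingness pattern with
adjusted df. Longitudinal change is reduced per subject to a rate map,
(t1 − t0)/months, tested with an intercept-only GLM; near-zero-variance
vertices are flagged NaN.

Cluster correction: the t/p map is thresholded two-sided at vertex
p < 0.01 with positive and negative clusters kept separately; cluster
extent is measured in mm² of vertex area. The null distribution comes
from n_iter (default 10,000) maps of unit white noise smoothed to the
residual-estimated FWHM (an explicit override is available), thresholded
identically, recording each iteration's maximum cluster area over both
signs. Cluster-wise p is the add-one estimator
(1 + #{null ≥ observed})/(1 + n_iter), never zero and monotone in area.
Each contrast is corrected independently; there is no cross-contrast
correction.

Two details of the null construction matter for calibration. First,
"smoothed to FWHM" is read as the resulting field's *measured* smoothness:
the kernel width is adjusted (one proportional correction against the
estimator's analytic expectation, computable from WWᵀ) so the null field
re-estimates to the target FWHM despite truncation and lattice
discretization. Second, null maps are standardized per vertex by the
operator's analytic output SD (√diag WWᵀ) rather than by a global SD.
Row-stochastic smoothing produces higher output variance near mesh
boundaries; a globally standardized null has a nonuniform marginal,
undersizes interior clusters, and inflated the measured familywise rate
to ≈0.038 at nominal 0.01 on the test conditions. With the per-vertex
standardization the null marginal is exactly unit normal — matching the
uniform marginal of the observed t map — and the measured familywise rate
is ≈0.007, i.e. at or slightly below nominal; the small residual gap is
the documented behaviour of comparing t-statistic maps against Gaussian
null fields at moderate degrees of freedom.

Residual smoothness is estimated from neighbor differences: for edges of
length h, Δ = E[(difference)²]/var, FWHM = h·√(−2 ln 2 / ln(1 − Δ/2)),
clamped to [mean edge length, 50 mm]. Two implementation details matter:
edges are bucketed by length before applying the formula (mixing lattice
and diagonal edges biases a pooled estimate), and moments are pooled
across maps after centering each vertex across maps — a per-map spatial
variance is deflated when the correlation length is not small relative to
the mesh, which underestimated smoothness by ~25 % on the test meshes.

Partial correlation residualizes both variables on covariates plus an
intercept and applies the Pearson test with df = n − 2 − k; with no
covariates it reduces to the plain Pearson test exactly. Composite
cognitive scores are per-test Z-scores against baseline means/SDs,
averaged in pairs: executive = (COWAT, CFT), psychomotor = (SRT, CRT),
memory = (CPAL, ISLT).

## Problem sizes and calibration checks

Test and acceptance runs use sizes chosen to make each claim measurable on
a single CPU while leaving the conditions fixed: straight-bundle phantom
24×20×16 at 1 mm; semicircle phantom 80×80×40 at 0.25 mm; parcellation
sphere 2562 vertices at K = 100; smoothing calibration on a 60×60 mm sheet
at 1 mm; cohort statistics on a 39×39 mm sheet at 1.5 mm (729 vertices),
20 subjects per group, noise SD 0.05 smoothed to 6 mm. Familywise error is
measured over 500 independent null cohorts at 1000 Monte Carlo iterations
each (the acceptance script reports a 200×500 version of the same
quantity); effect recovery uses a +0.1 mm⁻³ disc of radius 8 mm over 20
cohort seeds. The FWER check asserts the observed rate against the
binomial envelope of the nominal 0.01.

## Known limitations

- Euler stepping's outward drift bounds per-streamline length accuracy on
  curved bundles (see Tractography); a midpoint integrator would remove it
  but is not what deterministic FACT-style trackers do.
- Graph-geodesic parcellation distances and truncated smoothing kernels
  are approximations with small, characterized biases; exact polyhedral
  geodesics are out of scope.
- No spherical registration: template transfer requires an externally
  supplied correspondence.
- The null for cluster correction is Gaussian and stationary; heavy-tailed
  or nonstationary noise in real data is not modeled.
- Rates reduce the two-timepoint design exactly; there is no mixed-effects
  modeling for richer longitudinal designs.
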