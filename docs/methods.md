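# Methods

This note documents the registration model implemented by `siftreg`, the
choices made where the method description leaves room, and what the
synthetic phantom does and does not establish about clinical data.

## Coordinate model

All geometry lives in physical millimetres.  A volume is a 3D scalar grid
with voxel spacing, the physical position of the center of voxel
`(0,0,0)`, and an orthonormal direction matrix (the convention shared by
ITK, NIfTI and DICOM):

    physical = origin + direction · (spacing ∘ index)

Every estimated transform maps CBCT physical points into CT physical
space.  Thresholds (10 mm RANSAC stage 1, 5 mm stage 2, 10 mm local
search radius, 10 mm FOV margin) are physical distances and therefore
independent of the grids the volumes happen to be sampled on.

## Feature extraction

**Normalization.**  CT values are HU-like, CBCT values are uncalibrated;
both are mapped to [0,1] by clipping at the 1st/99th intensity
percentiles and rescaling.  This makes detection thresholds comparable
across modalities and exactly invariant to positive affine intensity
maps.  A caveat observed on phantoms: the upper percentile lands either
in the soft-tissue range or on bone depending on how much of the volume
bright bone occupies, which rescales soft-tissue contrast; the contrast
threshold is exposed in the configuration for such cases.

**Working grid.**  Both volumes are resampled to an isotropic working
grid before the pyramid, because scale sigmas in mm are ill-defined on
anisotropic clinical CT (slice thickness often 0.7–3 mm).  The default is
2.0 mm: abdominal structures of interest (vertebral corners, wall
calcifications, soft-tissue texture) are resolved at the corresponding
sigma_0 = 3.2 mm, and feature detection cost scales with voxel count.
Keypoint positions are reported in original physical space, so the
working resolution does not change the coordinate frame, only which
features are found.

**Scale space.**  Classic DoG pyramid: `levels_per_octave = 3`
(sigma ratio 2^(1/3) between levels), `s + 3` Gaussian levels per octave,
incremental smoothing, downsampling by 2 until the next octave would drop
below 16 voxels on some axis, `sigma_0 = 1.6` working voxels.  Sampled
discrete Gaussian kernels compose only approximately at sigma near one
voxel; the per-level absolute sigmas are bookkept exactly, and the
semigroup discrepancy (a few 1e-3 RMS on white noise) is far below the
DoG contrast threshold.

**Detection.**  Extrema over the 80-voxel scale-space neighborhood,
single-step quadratic sub-voxel refinement (offset −H⁻¹g, rejected
beyond 1.5 voxels), refined-contrast gate (default 0.02 on normalized
intensities), and a 3D blob test on the spatial Hessian: all three
eigenvalues of one sign with max|λ|/min|λ| ≤ 10, the 3D analogue of
Lowe's edge rejection that additionally removes plate-like responses.
The detection scale of an ideal Gaussian blob of width s in 3D is
√(2/3)·s — the closed-form maximizer of the DoG center response
σ²(s² + σ²)^(−5/2) — not s as in 2D; the tests use this oracle.

**Descriptors.**  For each keypoint, gradients of the Gaussian level
nearest its scale are accumulated into 4×4×4 spatial subregions ×
12 solid-angle orientation bins (icosahedron vertices, hard assignment),
length 768.  Each subregion spans 3σ voxels; samples are taken on a fixed
lattice with pitch σ (3 samples per subregion axis) rather than at every
voxel — the level is already low-pass at σ, so denser sampling adds cost
but no information.  Sample weights are trilinear in the subregion
coordinates times a Gaussian radial window (σ_win = half the window
width).  Histograms are normalized to unit norm, clipped at 0.2 per bin,
and renormalized; degenerate flat windows yield the zero vector.
Keypoints whose window lies entirely outside the grid are dropped.

**No orientation assignment.**  Descriptors are computed in the volume
axes.  Intra-patient CTA/CBCT pose differences are small rotations (both
supine), absorbed by the affine RANSAC; the descriptor bins are wide
(~63° solid-angle spacing), so rotations of ~10° move little mass between
bins.  This is a documented limitation: the features are not invariant to
large rotations.

## Matching and robust estimation

Mutual nearest-neighbor matching on descriptor Euclidean distance, ties
broken deterministically by lower index; no ratio test by default (the
mutual-consistency rule is the described filter).  The implementation
uses blocked BLAS distance computations and is tested for exact
agreement with an explicit all-pairs oracle.

RANSAC draws minimal samples of 4 correspondences, rejects near-coplanar
samples, counts inliers by residual ≤ threshold, adapts its iteration
count to the best inlier ratio at 0.99 confidence (cap 10,000), refits
the consensus set by least squares and recomputes the inlier mask.  A
consensus consisting only of the minimal sample (which any 4 matches
produce trivially) is not accepted when more matches are available — at
least one supporting match is required; this is what makes pure-noise
negative controls fail cleanly rather than "succeed" with 4 self-fitted
points.  An accepted affine must also have |det| in [0.5, 2]: larger
volume changes are anatomically implausible between acquisitions.

FOV pruning keeps CT features whose stage-1 pull-back lands inside the
CBCT grid's box dilated by the 10 mm margin, evaluated in CBCT index
space so oblique direction matrices are exact.  The box, not the inscribed
reconstruction cylinder, is used — conservative in the sense of keeping
more candidates (a cylinder test would be stricter; the margin already
dominates the difference).

## Thin-plate spline

3D TPS with kernel U(r) = r, the biharmonic fundamental solution in 3D
(r² log r is the 2D kernel).  The linear system is the standard
`[[K, P], [Pᵀ, 0]]` augmentation; the side conditions Σwᵢ = 0 and
Σwᵢcᵢᵀ = 0 fall out of the solve, making the radial part orthogonal to
affine maps — affinely related correspondences therefore give exactly
zero nonlinear weights, and the parameter count is 3N + 12 with a
12-parameter global affine block.

Note on regularization: U(r) = r is conditionally *negative* definite on
the side-condition subspace, so the smoothing variant perturbs the kernel
block as K − λI (with K + λI the system degenerates and residuals are
non-monotone in λ).  `fit_tps` with λ = 0 is the exact interpolant —
T(sourceᵢ) = targetᵢ to 1e-6 mm — and that contract is tested as such.

The *pipeline* default, however, is a stiff smoothing spline
(λ = 300 kernel units).  The rationale: each stage-2 inlier carries
feature-localization noise (~half a working voxel) and the 5 mm inlier
band admits occasional outright mismatches; a pure interpolant reproduces
every such error exactly at its control point, and on phantom batches the
interpolating TPS measurably *degraded* the landmark TRE relative to the
stage-2 affine — the opposite of what the final spline is for.  The
residual motion the spline must capture is smooth and organ-scale
(bump widths of tens of millimetres), which a stiff spline resolves
essentially unbiased while averaging single-correspondence noise away;
with smoothing, the TPS consistently matches or beats the affine and
self-registration stays within a fraction of a millimetre of identity.
λ is exposed in the configuration (0 restores pure interpolation).

The control points are the stage-2 inliers, deduplicated (sources within
1e-6 mm collapse to the first occurrence) and, if more than
`max_tps_points = 800` remain, subsampled uniformly with a seeded
generator — the dense TPS solve is O(N³) time / O(N²) memory and 800
well-spread points saturate the accuracy of a warp whose spatial scale is
tens of millimetres.

## Fusion

The estimated maps run CBCT→CT, so resampling the CBCT onto the CT grid
needs the inverse map.  The TPS is inverted per voxel by quasi-Newton
fixed-point iteration `p ← p − A⁻¹(T(p) − q)` with the stage-2 affine
linear part as constant Jacobian — the nonlinear part is small and
smooth, so this converges in a handful of iterations.  Voxels that fail
to converge fall back to the affine inverse; if more than 1% do, a
warning is recorded.  Only voxels whose affine preimage lands near the
CBCT grid are iterated at all (the rest are fill).  Trilinear
interpolation by default, nearest-neighbor by flag, fill value 0.

## Failure semantics

`register` returns an explicit result object: on failure it names the
failing stage (feature detection, mutual matching, either RANSAC stage,
FOV pruning, local matching, TPS fit), keeps everything computed before
it, and never raises for an unregistrable pair — batch evaluations can
tabulate failure modes.  Success requires at least 4 stage-2 inliers.

## The phantom: what it emulates, and what it does not

The generator reproduces the *geometric and radiometric structure* of
the clinical problem: FOV mismatch (250 × 250 × 190 mm cylinder inside a
360 × 360 × 480 mm CT, about 6.7× the volume), an inter-acquisition
affine pose change (rotation ≤ 10°, translation ≤ 30 mm, isotropic scale
within ±3%), a smooth nonlinear deformation (sum of ≤ 4 Gaussian
displacement bumps, σ ≥ 40 mm, peak amplitude ≤ 5 mm — analytic,
invertible at these amplitudes, and evaluable exactly anywhere), CBCT
intensity gain/offset plus additive noise, a contrast aorta present only
in the CT, and landmarks of the clinically used kinds (aortic-wall
calcifications, vertebral reference points).  The ground-truth map is
resampled (same random stream) until the mapped cylinder provably lies
inside the CT extent, so every generated pair is geometrically valid.

Scene intensities are schematic (soft tissue ≈ 40, bone ≈ 700,
contrast ≈ 1100, calcification peaks ≈ +800 over background, band-limited
texture SD 25, CT noise SD 5, CBCT gain 0.6 / offset 100 / noise SD 20
by default).  There is **no X-ray physics** — no scatter, beam hardening,
truncation artifacts, or streaks — and no real anatomical variability,
organ boundaries, bowel gas, or stent hardware.  Passing the phantom
suite therefore demonstrates that the pipeline implements the intended
geometry and is robust to the modeled nuisances at the modeled
magnitudes; it does not certify clinical accuracy on patient data.

Default test scale is 2.0 mm isotropic voxels for both volumes (clinical
CBCT is 0.5 mm; that remains a configuration option).  At 2 mm the full
ten-pair evaluation batch runs in a few minutes on one CPU; feature
localization error, and hence the TRE floor, scales roughly with voxel
size, so finer grids would lower the numbers further.

## Numerical details and edge cases

- Tie-breaking is deterministic everywhere (lower index wins); all
  randomness (RANSAC sampling, TPS subsampling, phantom generation) flows
  from explicit integer seeds, and fixed-seed runs are bit-identical.
- Duplicate keypoints (same position and scale within 1e-6) are collapsed
  to the strongest response; the feature cap keeps the largest
  |DoG response|.
- `fit_affine_lsq` requires ≥ 4 non-coplanar source points (rank checked
  via SVD); the TPS additionally rejects duplicate sources.
- Affine inversion and voxel/physical maps round-trip to 1e-9; TPS
  interpolation at λ = 0 reproduces its targets to 1e-6 mm.
- Landmark files are plain text `label x y z` (mm) with `#` comments;
  summaries use strict `<` threshold fractions and the
  midpoint-of-central-pair median convention.

## Known limitations

- No rotation invariance beyond what RANSAC absorbs (~tens of degrees).
- Percentile normalization couples detection sensitivity to the bright
  structure fraction of the volume (see above).
- The TPS is fitted where matches exist; extrapolation far outside the
  matched region reverts to the affine trend of the fitted data.
- DICOM is read-only; no 2D/3D fluoroscopy registration; no GPU path.
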