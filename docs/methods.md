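# Methods

This note documents what `peridvc` computes, the assumptions behind the
synthetic phantoms, the numerical choices that were genuinely open, and
what the validation suite does and does not demonstrate.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)`, 0-based, with z the screw/pullout axis.
All coordinates and displacements are kept in **voxels** internally and
converted to μm (distances) or με (strains) only at reporting
boundaries; this avoids unit drift inside the numerics. Intensities are
dimensionless gray values. Masked voxels carry NaN, never a sentinel
gray value, so no arithmetic can silently absorb them.

## Local DVC

Around each node of a regular cubic grid (default spacing 4 voxels), a
cubic subset (default 17 voxels per side) from the reference volume is
compared against the deformed volume at every integer offset in a cubic
search window (default ±3 voxels; at 25 μm voxels that is ±75 μm,
comfortably above the per-step motion of a stepwise pullout protocol).
The similarity metric is zero-normalized cross-correlation, computed
over voxels finite in *both* windows; ZNCC is invariant to affine
intensity changes between scans, which suits repeated tomographic
acquisitions. A node is reported only if

- at least `min_valid_fraction` (default 0.5) of subset voxels are
  jointly finite, and both valid windows have nonzero variance;
- the best score reaches `cc_min` (default 0.5) — otherwise the node is
  flagged `low_cc` rather than silently kept.

Ties in the integer argmax are broken by smallest offset norm, then
lexicographic (z, y, x), making results order-independent and
deterministic. Subpixel refinement fits a separable parabola through the
score and its two axial neighbors; the correction is clamped to
(−0.5, 0.5) per axis and is *skipped* when the integer optimum sits on
the window boundary or when the peak score is numerically perfect
(cc > 1 − 1e−9): a perfect match cannot be improved, and this guarantees
that noise-free integer rigid motions are recovered with exactly zero
error — a property the test suite asserts bitwise.

Implementation: the hot loop is a serial numba kernel. Fully finite
windows take a fast path using 3D integral images (window sums in O(1)
per offset); windows touching NaNs fall back to explicitly masked
accumulation. The node loop is serial, so fields are bit-identical
across runs and machines with the same inputs. Subset shape is
translation-only (no subset rotation or stretch): a first-order local
approach appropriate for small inter-step motions. Multi-scale pyramids,
global/FE-regularized DVC and GPU execution are out of scope.

## Strain

Displacements are first median-filtered componentwise on the node grid
(default radius 1 node, a full 3×3×3 neighborhood; failed nodes are
excluded from each sample). Each grid cell then forms an 8-node
hexahedral element with trilinear shape functions, and the deformation
gradient F = I + ∂u/∂X is evaluated once at the element center (the
center gradient along each axis is the mean of the four corner-pair
differences divided by the node spacing). One evaluation point per
element matches the map resolution of the displacement grid (100 μm at
spacing 4 × 25 μm); Gauss-point averaging would add nothing at that
resolution. From F:

- Green–Lagrange tensor E = ½(FᵀF − I), stored as the six components
  (εxx, εyy, εzz, εyx, εzx, εzy) with εyx = εxy etc.;
- volumetric strain det(F) − 1;
- maximum shear strain
  γ = ⅓ √(2(εxx−εyy)² + 2(εxx−εzz)² + 2(εyy−εzz)² + 12εyx² + 12εzx² + 12εzy²).

The γ formula is implemented with exactly these coefficients (leading ⅓,
factors 2 and 12). With them, γ ≥ 0 always and γ = 0 iff E is isotropic;
whether the classical octahedral-shear constant (2/3) was intended
instead is a known ambiguity, and the printed coefficients are kept
deliberately. For u linear in X, trilinear elements reproduce the
imposed F exactly in every element; rigid rotations give E = 0 to
machine precision. Elements with any failed corner node are flagged and
carry NaN.

## Repeated-scan error protocol

Accuracy is the mean and precision the (population) standard deviation
of each displacement component over ok nodes, between two scans of an
unchanged specimen, converted to μm. For strains, the absolute values of
all six components are pooled across valid elements and their mean and
standard deviation reported in με — a single accuracy/precision pair, not
per-component, matching how such errors are conventionally summarized.
Element-level strain samples are used (the only strain field that
exists).

## The phantom generator

The generator emulates a 25 μm-voxel tomogram of peri-implant trabecular
bone, not any particular animal's anatomy:

- **Trabecular texture**: a Gaussian random field (white noise smoothed
  with a Gaussian of σ = half the texture scale, default 150 μm)
  thresholded at the quantile that yields the target solid fraction
  (default 0.32, the peri-implant value for this screw-ingrowth model).
  The quantile construction calibrates BV/TV by construction; the
  texture scale is a free parameter chosen to give strut dimensions of
  order 100–200 μm and is not a claim of anatomical fidelity.
- **Scanner blur**: the two-level field is smoothed with a Gaussian PSF
  (default σ 0.8 voxel). Without band-limiting, the correlation peak of
  a binary image is triangular and parabolic subpixel interpolation
  locks onto integer voxels; real reconstructions are band-limited.
- **Screw**: an axisymmetric threaded cylinder along z (triangular
  thread profile, default 400 μm pitch, 150 μm depth, outer radius
  default 1300 μm = the Ø 2.6 mm implant), overwritten at the screw
  intensity, with its mask kept for downstream masking and ROI
  definitions.
- **Warps**: displacement u is defined in the reference frame and the
  deformed image resampled as `deformed(x) = reference(x − u(x))`
  (trilinear), matching the reference→deformed tracking direction of
  subset DVC, so the imposed u *is* the ground truth DVC should return.
  Integer rigid translations are applied by exact index shifts (no
  interpolation). Voxels pulling from outside the domain become NaN, so
  masking is exercised. The `pullout_envelope` warp displaces material
  within 300 μm of the screw surface axially by a set magnitude
  (default ground truth: 4 voxels = 100 μm) with a cosine taper to zero
  over a further 400 μm — the displacement shell seen around a pulled
  screw, with an analytic shear maximum at the taper midpoint.
- **Noise**: additive zero-mean Gaussian, default std 5% of the
  bone–background contrast for error studies, independent between scans.

What the phantom does **not** model: x-ray projection physics, metal
streak/beam-hardening artifacts, cortical bone, marrow/soft-tissue
intermediate gray levels, or anatomically realistic trabecular
morphology. Passing the validation suite therefore shows the *analysis
chain* is correct on known ground truth under realistic noise; it does
not certify error magnitudes on artifact-laden scans near a real metal
interface, where errors are typically larger.

## Desk-scale study conditions

Validation runs use a 128³ phantom (3.2 mm cube at 25 μm). A full-size
scan of this protocol covers ~20 mm (800³ voxels), which is unnecessary
for validating the numerics. Inside a 3.2 mm cube, the 1300 μm screw
radius would leave no room for the standard ROI (a 0.5 mm shell beyond
the screw maximal radius, 2.2 mm axial span), so the validation phantom
scales the screw to 600 μm radius while keeping the protocol's ROI
offsets, voxel size, grid settings and solid fraction unchanged. The
repeated-scan experiment correlates ~17,500 nodes; the envelope
experiment uses search radius 5 voxels to cover the imposed 4-voxel
motion. These conditions are fixed in `peridvc.experiments` and used by
both the test suite and `scripts/acceptance.py`.

## Other numerical choices

- **Image median filter** (default radius 4 voxels, before
  binarization): spherical neighborhood, NaN-excluded sample, brute-force
  verified. Note that radius-4 filtering visibly erodes the phantom's
  thinner struts (it lowers measured BV/TV by several points on
  synthetic textures); the morphometry validation therefore binarizes
  the unfiltered phantom, while the pipeline default keeps the filter
  for real scans, whose noise structure is what the filter exists for.
- **IsoData threshold**: fixed-point iteration t ← (mean below + mean
  above)/2 from the global mean, convergence at 0.5 gray level.
- **Screw-axis alignment**: principal component of the screw-mask voxel
  coordinates; refuses masks with axis ratio < 1.2. Order of the
  preparation chain is filter → align → threshold/mask.
- **Masking thresholds**: on phantoms, IsoData between background and
  bone plus the bone/screw midpoint; for real scans they are required
  configuration inputs.
- **Stiffness fit**: least-squares slope of force vs displacement over
  the 20–80% window of the force span on the loading envelope
  (relaxation holds detected by near-zero crosshead velocity and
  excluded); failure is the first sample below 0.9 of the running force
  maximum. The window and drop fraction are configurable because no
  single convention exists.
- **BV/TV ROI membership** is decided by voxel-center coordinates, and a
  ROI extending beyond the volume is refused rather than truncated.
- **Determinism**: every generator and the DVC engine are pure functions
  of (inputs, seed); the pipeline manifest records a config hash, and
  cached displacement fields round-trip through CSV at full float64
  precision so cached and fresh runs agree bitwise.

## Known limitations

- Subpixel bias of parabolic peak interpolation is reduced but not
  removed by PSF blur; gradient-based subset optimization would lower
  it further and is deliberately out of scope.
- The DVC map inherits the node grid: displacements are unavailable
  within the subset+search margin of the volume boundary and inside
  masked phases.
- The strain field treats the displacement grid as a continuum; cracks
  appear as bands of high apparent strain rather than explicit
  discontinuities.
- `align_screw_axis` resamples once (trilinear); repeated alignment of
  already-aligned data slowly blurs the volume.
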