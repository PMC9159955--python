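# Methods

This note documents the models, parameters and numerical choices behind
`dermatrace`, and what the synthetic validation does and does not show.

## Coordinate and data conventions

Image arrays are `(z, y, x)` with one TIFF page per z plane; voxel indices
are 0-based and z = 0 is the skin surface. Physical positions are
`(x, y, z)` triples in µm (`index × voxel_size`); the default voxel is
0.427 × 0.427 × 1.0 µm, matching stage-scanned two-photon acquisition at
427-nm pixels and 1-µm steps. All lengths are reported in µm. Fiber graphs
live in physical coordinates so they survive registration resampling.

## Synthetic skin-innervation model

The simulator generates the study conditions for every quantitative check.

**Fiber forests.** Trees grow from dermal roots toward the surface as
discrete random walks (step 1.5 µm, directional jitter 0.35, upward drift
0.35, mean 3 side branches at ±35° take-off s.d.). Two caliber classes:
*thin* nociceptor-like trees (radius 0.25–0.45 µm, gentle taper) terminate
in short filopodia-like endings above the dermal–epidermal boundary; *thick*
Aβ-like trees (1.2–1.8 µm) end in coiled, corpuscle-like terminals 1.5–5 µm
below it. A node is epidermal exactly when its z is shallower than the
boundary depth (default 15 µm). Defaults of 4 thin + 3 thick trees populate
the 192 × 192 × 48-voxel (82 × 82 × 48 µm) validation scene at a realistic
density; an acquisition-scale preset (2,000 × 2,000 px, thin z) with many
laterally wandering fibers serves the stitching checks.

**Rendering.** Tubes are hard disks of the local radius convolved with an
anisotropic Gaussian PSF (σ = 0.3 µm lateral, 1.0 µm axial). The intensity
uses anti-aliased partial-volume coverage (a detector integrates over the
voxel), while the ground-truth label volume is the exact center-in-tube
test, so label counts equal a brute-force point-in-tube enumeration. The
epidermal autofluorescence band (default 0–15 µm deep, amplitude 20 photons)
carries smooth texture with ~25 % carved-out gaps; hair-like appendages are
bright tilted cylinders descending from the surface (150 mm⁻², 55 photons).
Expected photon counts (background 3, fiber 45) are multiplied by a linear
surface-to-depth excitation ramp (default 3×, emulating laser power ramped
from 5 % to 15 %), then Poisson shot noise and Gaussian read noise
(σ = 1 photon) are applied and the result is digitized at 250 DN/photon to
16 bits. These amplitudes give thin-fiber peak SNR ≈ 4 and thick ≈ 7 at the
surface — deliberately unglamorous, in-vivo-like conditions.

**Longitudinal change.** Later sessions remove a per-caliber fraction of
trees; regrown trees reuse their stored baseline centerlines with smooth
sub-µm jitter (sprouting retraces the original trajectories). Removal and
regrowth subsets are prefixes of a seed-keyed permutation, so a larger
fraction always extends a smaller one — regrowth is cumulative, which also
guarantees the monotonicity of percent-of-baseline metrics. With epidermal
entry suppressed, regrown thin trees are truncated 2 µm below the boundary
(retraction stalling under the basal membrane). Each session receives a
fresh rigid motion (≤2°, ≤4 µm) plus a sum of low-frequency sinusoidal
displacements (2 µm amplitude) whose total slope is kept below 1 so the map
cannot fold.

## Stitching

Seam offsets between neighbouring tiles come from `skimage` SIFT keypoints
matched on the z-MIPs of overlap-facing strips (nominal overlap + a 50 %
search margin), with a single translation taken as the mean of matches that
agree with the median within 2 px (≥5 inliers required). A deterministic
normalized cross-correlation search over the nominal overlap ±25 % is the
fallback for feature-poor scenes. The mosaic is hardcoded 2×2,
translation-only; sub-pixel estimates are rounded before copying; overlap
strips are blended with linear ramps of the overlap width so non-overlap
voxels are copied bit-exactly. The bottom-right tile origin averages the two
consistent seam routes.

## Segmentation and autofluorescence removal

Per-voxel features (intensity, large-scale brightness, local-background
contrast, window variance, two tubularity scales, weighted depth and lateral
position) are augmented with the leading eigenvectors of the normalized
Laplacian of a 4×-downsampled lattice graph whose affinities are Gaussian in
intensity and texture (fixed ARPACK start vector for determinism). Sparse
seeds — automatic by default: dim voxels → background, low-contrast laminar
surface signal → band, noise-significant ridges (≥5 σ contrast, and locally
out-shining the band's own texture) → fiber, surface-connected bright cores
→ appendage — are propagated by distance-weighted k-NN in feature space;
probability maps are smoothed by Perona–Malik diffusion (κ = 0.3, dt = 0.15,
5 iterations; total variation never increases) and seeds always keep their
label. A scene with almost no confident fiber candidates gets no fiber class
at all: a fully denervated territory must not grow fibers out of band
texture.

Because propagation claims the PSF halo, the fiber class is refined with the
imaging model: the image is flattened by per-slice background medians,
Richardson–Lucy deconvolved (15 iterations) with the known PSF, pooled along
the local fiber direction (max of oriented line averages, 3 µm), and each
candidate component is cut at half of its deconvolved peak — the
half-maximum contour of a disk is the disk edge. A tube model built on the
centroid-refined skeleton of that mask, with radii from the flux theorem
r = √(F/πA) (integrated excess brightness per unit length is
blur-invariant), prunes the remaining halo. Inside the band, fiber survives
only where it is rooted in dermal fiber or clearly out-shines the band;
rooted components whose in-band bulk dwarfs their dermal part are treated as
band texture except immediately at the crossing stub.

Two artifacts are emitted: the voxel-accurate label volume (used for
removal and accuracy scoring) and a topologically continuous trace mask
(the pooled half-max mask) for skeletonization — one mask cannot serve both
purposes, because the voxel-optimal pruning leaves thin shells that break
3D thinning. Removal replaces band/appendage voxels with the per-slice
median of background voxels.

On the validation scene the removal clears >99 % of band voxels while >97 %
of fiber voxels keep their values; voxel-wise fiber precision is ≈0.90 and
recall ≈0.86. The recall ceiling is informative: even an oracle threshold on
the noiseless render tops out near 0.88/0.88, because a 1-µm axial PSF on
0.25–0.45-µm fibers genuinely erases voxel-exact boundary information.

## Intensity conversion

The conversion model is `DN = dark(z) + gain(z)·signal`: a per-slice dark
level (the slice low percentile — detector offset plus dim scattered light)
is subtracted, the multiplicative depth gain is fitted log-linearly on an
inter-quantile trimmed slice statistic (background-excluded below,
clip-insensitive above) and divided out, and the flattened signal is
stretched to [0, 255] by the global high percentile (99.5). Every step is
scale-equivariant, so stacks differing by a global gain convert identically,
and the composition is exactly idempotent (re-converting a converted stack
changes no voxel by more than one grey level — on the validation scene, by
zero). A per-slice window blend is available (`local_blend`) but defaults to
0: any non-trivial per-slice restretch is incompatible with idempotence, and
depth adaptivity is already carried by the gain fit. Cross-session
normalization maps each session's robust foreground anchor percentiles
(50th/99th above the 75th-percentile floor) affinely onto the baseline's
before conversion.

## Registration

Suprathreshold fiber voxels (in the pipeline: the segmentation's fiber mask)
become µm point clouds, subsampled to ≤15,000 points. Trimmed ICP (keep
fraction 0.7, coarse-to-fine, closed-form Kabsch updates) minimizes
J = Σ‖T(P) − Ψ(P)‖ over the best correspondences; the recorded residual
history is per-stage and non-increasing; collinear clouds fall back to a
translation-only fit with a warning. The thin-plate spline (3D kernel
U(r) = r, bending regularization λ = 10) refines on ≤200 mutually-nearest
correspondences no farther than 5 µm apart; a warp whose 95th-percentile
displacement over the source cloud exceeds 6 µm is rejected in favour of the
rigid fit — unconstrained extrapolation of a sparse-landmark spline can
stretch traced geometry severely. All sessions register to the baseline;
common-volume cropping intersects the transformed bounding boxes and
resamples trilinearly (nearest-neighbour for labels).

## Tracing

scikit-image 0.26's 3D thinning erases solid objects (a rod thins to
nothing), so the package carries its own distance-ordered homotopic
thinning: border voxels are deleted outside-in, each deletion gated by
Bertrand's simple-point test (foreground 26-topology and background
6-topology preserved) with endpoint preservation; the mask is z-upsampled to
near-isotropic voxels first so thick tubes do not degenerate into medial
surfaces. The skeleton becomes a graph (junction/end voxels as nodes,
degree-2 chains as polyline edges; closed loops split via midpoint nodes so
no self-loops exist); terminal twigs shorter than 3 µm are pruned; end
pairs whose terminal path segments come within 5 µm and whose smoothed
outward tangents (measured 1.5–5.5 µm behind the tip, skipping the blunt-end
hook) lie within a 30° collinearity cone are bridged, and every bridge is
recorded with its gap and angles for auditing. Radii are per-slice 2D
distance transforms sampled along edge paths (3D distances are floored by
the 1-µm slice spacing); caliber is the length-weighted median edge radius
per component against a 0.8-µm threshold, ties thick. Components shorter
than 8 µm are dropped as speckle. Tracing is fully deterministic.

## Quantification

Lengths clip polylines to the ROI exactly (per-segment parametric
clipping). Endings are degree-1 nodes farther than 3 µm from every analysis
face. The dermal–epidermal surface is the per-column deepest band voxel,
debiased by one axial PSF extent, with outlier columns (appendage shafts
misclassified as band) replaced by the global level and a 9-px median
filter — the junction is laterally smooth. Intra-epidermal free endings are
terminal branches ending above the surface; in pipeline use they must also
emanate from below it (a free ending belongs to a fiber crossing the
junction), with a 3-µm surface margin matching the registration error
budget. Percent-of-baseline metrics are evaluated inside the volume common
to all registered sessions; a zero baseline yields an undefined marker, not
an error. Change maps classify edges by bidirectional polyline proximity
(median point-to-curve distance ≤3 µm), partitioning each session's edges
into stable/lost or stable/gained exactly once. Ending densities per area
and per volume are both derivable from the common ROI box.

## Pipeline and reproducibility

`run_pipeline` executes simulate-or-load → (optional tiling + stitching) →
segmentation/removal → conversion → registration-to-baseline → tracing →
quantification. Every stochastic stage draws its seed deterministically from
the master seed by hashing the stage name and session label, so adding
stages never perturbs earlier ones; the report JSON records all parameters
and seeds, and rerunning a configuration reproduces the metrics CSV byte for
byte.

## Validation scope and limitations

The end-to-end validation runs the five-session SNI timeline at
192 × 192 × 48 voxels, the package's standard scene for full-pipeline
checks (single-stage checks use the same or smaller scenes). Passing it
shows that the chain recovers the qualitative structural time course —
thin-fiber collapse below 10 % and recovery above 80 % of baseline,
persistent thick-fiber absence, persistent absence of intra-epidermal
endings — from rendered images alone, under the simulator's assumptions.

What it does not show: absolute length accuracy on real tissue. Traced
length underestimates coiled terminals and in-band arbors and can
overestimate late-regrowth sessions (band texture adhering to
boundary-crossing stubs, plus non-rigid warp stretch), so percent-of-baseline
values above 100 % occur; the validated read-out is the time-course shape,
not the absolute percentage. The simulator also omits blood vessels, immune
and Schwann cells, motion artifacts within a stack, and any photorealistic
optics beyond a Gaussian PSF; real autofluorescence is more structured than
smoothed noise. Voxel-exact fiber-boundary recovery is information-limited
by the axial PSF (recall ≈0.86 against the geometric ground truth), which
bounds what any segmentation can achieve at this geometry.
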