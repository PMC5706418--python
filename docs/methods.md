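# Methods

## Measurement model

A field of view is a pair of co-registered single-channel z-stacks — cell
membrane stain and scaffold stain — on a common `(z, y, x)` voxel grid with
anisotropic physical voxel size, default `(dz, dy, dx) = (0.462, 0.12,
0.12)` µm as acquired by a 63× water-immersion confocal. Contact is an
object-level notion: a voxel is a contact site when cell and scaffold
labels co-occur there or sit within one voxel of each other
(26-connectivity by default, configurable to 6/18). All intensity
processing happens in floating point; 16-bit unsigned is the on-disk
format, and voxel size is metadata only — nothing is resampled implicitly.
Physical units enter exactly where the measurement requires them: plane
residuals (nm) and fiber radii (µm).

## Statistical foreground models

The background intensity model `(µ_BKG, σ_BKG)` is the mean/std of the
first (or last) z-frame, which images medium rather than stained
structure; a guard warns when ≥ 1% of that frame exceeds 10× its median.

* **A1 (single pixel).** `P = Φ((I − µ_BKG)/σ_BKG)`, the Gaussian
  upper-tail posterior. By construction this is 0.5 at the background
  mean — A1 separates classes but never drives background probability to
  zero; tests therefore check separation for A1 and absolute levels only
  for A2–A5.
* **A2 (mixed pixel, spatial).** Partial-volume fraction
  `α = clamp((I − µ_BKG)/(I_FRG − µ_BKG), 0, 1)` with `I_FRG` the 99th
  percentile of the A1-positive set (A1 posterior binarized by the
  maximum-entropy criterion), mean-pooled over a 3×3×1 in-plane
  neighborhood (z slices are ~4× coarser than x/y).
* **A3 (mixed pixel, channel).** Estimates the cross-channel bleed
  coefficient and applies A2 to the unmixed intensity. The coefficient is
  the median of per-voxel ratios `(I_target − µ_t)/(I_partner − µ_p)` over
  strong partner-foreground voxels (> 5σ above background). A
  least-squares fit restricted to "partner-positive, target-negative"
  voxels fails at realistic bleed levels because the leaked signal itself
  triggers the target channel's foreground detector; the median-of-ratios
  form is robust whenever bleed-only voxels are the majority, and recovers
  a synthetic mixing coefficient of 0.3 to within 0.05.
* **A4 (additive noise).** Two-component Gaussian mixture with the
  background component pinned to the background model; the foreground
  component is initialized from the A1-positive set and refined by EM; the
  posterior responsibility is the probability.
* **A5 (Markov random field).** Ising-regularized A1 posterior: iterated
  conditional modes on hard labels (6-neighborhood, β = 1.0, ≤ 10
  sweeps, replicated borders), followed by one soft readout
  `sigmoid(logit(P_A1) + β Σ(2·label_n − 1))` so the returned volume is a
  probability map rather than a hard mask.

Class priors use K-means (K = 3) on the (cell, scaffold) intensity
scatter. Centroid identity is structural: background is the centroid
nearest the origin; of the remaining two, the one with the larger
cell-channel coordinate is the cell. Per-voxel probabilities are relative
inverse distances `P_c = (1/d_c)/Σ_j(1/d_j)` with an exact-hit
short-circuit, which satisfies the sum-to-one constraint and the
centroid/equidistant limits exactly. Clustering is seeded deterministically
(recorded seed; up to 5 re-seeds on a degenerate solution) and subsampled
above 2^24 voxels.

The maximum-entropy threshold builds an `n_bins = 256` histogram over
`[min, max]`, splits it at every interior bin edge, and maximizes the sum
of Shannon entropies of the renormalized halves; ties take the first
(lowest) maximizer and the mask is `volume ≥ T_opt`. Constant volumes are
rejected.

## Geometrical models

**Plane (spun coat).** The film surface sample of each (y, x) column is
its extreme-z voxel with weight ≥ half the column maximum — the
half-maximum crossing marks the edge of a blurred film, whereas the
outermost above-noise voxel rides the blur tail and biases the plane
upward by 1–2 voxels. Weights default to normalized intensity above
background, floored at `µ_BKG + 3σ_BKG`; unit weights are supported so the
residual formula can be exercised exactly. The plane minimizes
`Σ w·f(x,y,z)²` subject to a unit normal (weighted-covariance
eigenvector). The residual standard deviation is

    STD_k = sqrt( Σ_i w_ki f_k(x_i,y_i,z_i)² / (Σ_i w_ki − w̄_k·p) ),  p = 3,

with `w̄_k` the mean weight *of the points entering the fit* — taking the
mean over all voxels of the stack (mostly zero-weight background) would
collapse the degrees-of-freedom correction; with unit weights the
denominator is the classical `n − p`. Residuals are reported in nm. The
pooled statistic over K stacks is
`sqrt(Σ(n_k − 1)·STD_k² / (Σn_k − K))`, which reduces to `STD_1` at K = 1.
Whether the upper or lower film surface is fitted defaults to the surface
nearer the cell centroid.

**Vesselness (fibers).** The Hessian is computed by Gaussian-derivative
convolution at scale σ expressed in voxels of the finest axis; z
derivatives are rescaled by `dz/dx` so the filter acts isotropically in
physical space. The response is the standard Frangi bright-tube form with
α = β = 0.5 and `c` = half the maximum Hessian Frobenius norm. σ = 1.0
(method A6) and σ = 1.5 (A7) are dimensionless filter scales. The
binarization threshold is learned on the full-volume response and the
resulting mask is then restricted to the cell neighborhood: thresholding
the cell-masked response directly would, in a scaffold-free neighborhood,
split pure noise and fabricate contacts. A8 thresholds raw intensity, then
applies a 3×3×3 median filter and removes components under 27 voxels.

**Contact surface.** Central-difference 3-D gradient of the binary,
cell-masked scaffold segment; surface voxels are segment voxels with
nonzero gradient magnitude (so the surface is a subset of the segment
boundary — an isolated single voxel has no central-difference support and
yields an empty surface). Volume-border voxels are excluded: the crop
boundary is not a physical surface.

## Preprocessing

Cell segmentation is deliberately simple — maximum-entropy threshold,
largest 26-connected component, per-slice hole filling, one 3×3×3 binary
closing — sufficient to supply the single compact cell mask the cropping
and contact stages need. It is exact on blur-free phantoms and
over-segments by roughly the blur width otherwise.

ROI cropping expands the cell bounding box by 10% of its width/height per
x/y side (clipped to the volume; degenerate boxes are padded to 8 voxels
with a warning). The z interval comes from the scaffold channel's
z-profile: per-frame maximum of the [X, Z] projection, smoothed with a
length-21 Gaussian (σ = 5, reflected ends); bounds are the zero-crossings
of the second derivative nearest below/above the profile argmax, falling
back to the volume edge (with a warning) when a side has none, and widened
if needed so the cell itself is covered. Stacks under 25 frames are not
cropped in z.

## Synthetic phantoms

The generator emulates the image-formation chain: analytic geometry
(plane-bounded slab; cylinders of given axis, direction, radius;
ellipsoidal cell) is rasterized by the voxel-center rule — no
antialiasing, so analytic position/volume oracles are exact — then blurred
with a separable anisotropic Gaussian standing in for the PSF (default
(0.6, 0.2, 0.2) µm, matching the stated optical resolution scale), mixed
across channels with a single symmetric linear bleed coefficient, offset
by a constant background, and corrupted by i.i.d. Gaussian noise from a
seeded generator. Ground-truth masks come from the pre-blur geometry;
the truth contact mask applies the same co-occurrence/adjacency rule as
the measurement.

Defaults follow the study design the package targets: large-microfiber
radius 1.3 µm and medium-microfiber radius 0.55 µm (nominal diameters
2.6 / 1.1 µm), background offset 200, noise σ 30 (foreground intensities
3000–5000, i.e. SNR ≫ 5). No measurement of the bleed coefficient exists
to calibrate against, so the bleed fixture uses 0.3 — strong enough that
naive single-channel thresholding demonstrably mislabels pure-cell voxels
as scaffold. What the phantoms do **not** emulate: depth-dependent PSF
variation and optical distortion, stain-specific emission spectra,
photobleaching, multi-fiber mats with realistic density, or stitched
multi-FOV acquisitions. Passing phantom tests therefore demonstrates
correctness of the measurement chain under the stated image-formation
model, not performance on real microscope data.

## Fiber validation

Skeletonization is 3-D medial-axis thinning; the skeleton graph is
decomposed into degree-2 chains between terminals, tangents are ±2-point
central differences along each chain in physical coordinates, and branch
points are counted as 26-connected clusters of degree > 2 voxels (thinning
can represent one junction by a few adjacent voxels). At each skeleton
point — excluding points within 3 voxels of a branch end, where the medial
radius is ill-defined — 16 rays at equal angles in the normal plane march
in steps of a quarter of the smallest voxel dimension until they exit the
mask; the radius is `sqrt(2·λ_min)` of the boundary-point covariance.
For points uniformly distributed on a circle of radius r both in-plane
covariance eigenvalues are r²/2, so the calibration is exact in the
continuous limit; a raw "smallest eigenvalue" would carry units of
length². On rasterized cylinders of radius ≥ 4 voxels the estimator is
within 10% (typically ~2%) across random orientations. Rays that never
exit the mask inside the volume skip the point and are tallied. The
ALL/Internal distinction is implemented as an interior sub-box
restriction; multi-FOV stitching is out of scope.

## Evaluation

Probability maps are compared with `d = sqrt(Σ(p_i − p_j)²/XYZ)`, an L2
metric bounded by 1 on probability volumes. An optional 8-bit scale flag
multiplies by 255 before the distance, solely for comparison against tools
that report the statistic on quantized maps; it is non-canonical.
Verification accuracy is the fraction of items with at least one positive
expert label (cells: good/correct; contacts: excellent/acceptable);
precision is the mean over expert pairs of their agreement ratio after
binary grouping, excluding (with a warning) pairs with no shared items.

## Problem sizes and determinism

The fixture suite uses 24×64×64 volumes, chosen so that the full test
suite and the acceptance script each complete in seconds while every
geometric feature (fiber cross-section ≥ 4 voxels, slab, cell) remains
well resolved. Fixed seeds make phantoms bitwise reproducible and the full
pipeline byte-deterministic; every run report embeds its effective
configuration and seed.

## Known limitations

* The simplified cell segmentation over-segments blurred boundaries by
  ~1 blur width; the permutation-optimized segmentation it stands in for
  is out of scope.
* A1's background probability plateaus at 0.5 by construction (see above).
* The Frangi response uses the standard constants; any proprietary
  modification of the filter is not reproduced.
* Bleed-through correction assumes linear, spatially uniform mixing.
* Plane fitting assumes one dominant film surface per column; films with
  folds would need per-region fits.
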