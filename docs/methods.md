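# Methods

## Problem setting

Light-sheet fluorescence microscopy of whole embryos degrades with depth:
scattering of visible-wavelength emission blurs and attenuates the image the
deeper the detection plane sits below the sample surface. When the same
sample carries a second, scattering-resistant channel (for example a
near-infrared dye bound to the same structures), the two co-registered
volumes form a supervised training pair: the visible channel is the degraded
input, the infrared channel the ground truth. This package implements that
supervised restoration workflow end to end — training-pair construction,
patch registration, network training, tiled prediction and quality
assessment — together with a synthetic phantom so every stage can be
exercised and tested without microscope data.

All volumes are single-channel 3D grids in plane-major `(z, y, x)` order with
per-axis voxel spacing in µm. Patch shapes, centers and offsets use the same
axis order; a patch centered at `c` occupies `[c - p//2, c - p//2 + p)` per
axis.

## Selective patch sampling

Voxels are split into foreground/background by an Otsu threshold (histogram
of 256 bins over the min–max range; the threshold is the upper edge of the
last background bin, ties broken toward the lower cut; foreground means
*value > threshold*). The per-voxel extraction probability is

    P = B / N_f   (foreground),      P = (1 - B) / N_b   (background),

with `B` the total foreground mass (default 0.9, i.e. ~10 % of patch centers
fall on background) and `N_f`, `N_b` the class counts. `B = N_f / N`
recovers the homogeneous distribution `P = 1/N` exactly.

Border handling: centers whose patch would not fit inside the volume are
excluded and each *class* is renormalized separately, so the foreground mass
stays exactly `B` whenever both classes survive the restriction. (A single
joint renormalization would silently shift the realized foreground fraction
whenever the border clips the two classes unevenly; preserving the class
masses keeps the sampling law exact, which is also what the 10 %-background
design intends.) A class with no admissible voxel cedes its mass to the
other.

Extraction draws centers in batches of 50 (sampling with replacement —
duplicates allowed, coverage unaffected) and stops when *sample coverage* —
the fraction of foreground voxels covered by at least one extracted patch —
reaches the target (default 95 %), or at `max_patches`, which flags a warning
status instead of raising. The coverage trace is non-decreasing by
construction.

## Patch registration

Residual chromatic misalignment is corrected per patch by exhaustively
maximizing the zero-mean, unit-variance (Pearson-style) cross-correlation
`C(dz, dy, dx)` over an integer search box (default radius `(2, 10, 10)`
voxels in `(z, y, x)`). Correlation is evaluated on the shrinking overlap
only — no zero padding — so border artifacts cannot fabricate maxima. Ties
break toward the smallest offset norm, then lexicographically, making
results platform-deterministic. No subvoxel interpolation is attempted; the
offsets this corrects are integer-scale chromatic shifts.

## Restoration network and training

The regression network is a compact volumetric U-Net: two pooling levels,
3×3×3 convolutions, 2× max pooling on all axes, nearest-neighbour
upsampling with skip concatenation, and a linear 1×1×1 output head. It is
implemented directly on numpy (im2col + GEMM with hand-written
backpropagation, Adam optimizer), which keeps desk-scale training in the
minutes range on a single CPU core.

Numerical choices that matter:

* **Leaky ReLU (negative slope 0.1)** instead of hard ReLU. In networks this
  small the final decoder layer can die irrecoverably during the early
  learn-the-mean phase of optimization, pinning the output at a constant;
  the leaky slope removes that failure mode. The output head is linear — a
  softmax over a single channel would be identically 1 and cannot regress
  intensities.
* **He-style initialization**, scaled down on the linear head; Adam at
  learning rate 4e-4 (the framework default for this kind of image
  regression; nothing in the workflow is sensitive to it at ±2×).
* **Normalization**: inputs and targets are affinely mapped by the 0.3/99.9
  percentiles of their nonzero support, one constant pair for the pooled
  inputs and one for the pooled targets; the same constants un-normalize
  predictions. A single percentile convention is used everywhere (training,
  difference maps).
* **Split and schedule**: random disjoint 9:1 train/validation split,
  mean-squared-error loss, fixed epoch count (full-scale default 100,
  batch 8; no early stopping). All randomness flows from explicit seeds, and
  single-threaded runs reproduce loss traces exactly.

Whole volumes are restored by tiled inference: tiles at a fixed stride (tile
minus overlap), per-axis linear feather weights in the overlap zones,
weighted accumulation, then division by the accumulated weight. Constant
predictors are exactly seamless; smooth predictors agree across tilings to
~1e-3 in normalized units away from borders. Axes smaller than one tile are
reflect-padded and cropped back.

## Quality metrics

* `NRMSE(x, y) = sqrt(<(x - y)^2>) / <y>`.
* `pearson(x, y)`: product-moment correlation of flattened intensities,
  evaluated on patches picked to avoid dark regions (foreground centers).
* `ssim(x, y)`: structural similarity with Gaussian-weighted local windows
  (σ = 1.5, k1 = 0.01, k2 = 0.03), delegated to scikit-image;
  `data_range` defaults to the span of the reference. For 3D patches thinner
  axially than the 11-voxel window, per-plane 2D SSIM is averaged instead.
* Information content `IIC = -Σ p_ij ln p_ij` with `p = F / Σ F` and
  `F = DCT(I)^2 / N^2` (orthonormal type-II DCT). The `N^2` divisor is kept
  for fidelity to the definition although it cancels in `p`. The formula
  indexes a 2D spectrum while patches are 3D: the default evaluates the 2D
  DCT per z plane and averages plane entropies (consistent with plane-wise
  kymographs); a full-3D mode is available and coincides with the default on
  single-plane patches. Conventions: an all-zero patch has IIC 0; `0·ln 0 = 0`;
  `0 ≤ IIC ≤ ln M` for `M` coefficients; `IIC(α·patch) = IIC(patch)` for
  α > 0. The *information-content gain* of image a over image b is
  `IIC(a) / IIC(b)`.
* Surface-proximal selection: the sample mask comes from a manual threshold
  or Otsu; the edge shell is the mask minus its binary erosion; voxel
  distances to the shell use the anisotropic Euclidean distance transform.
  Patch eligibility uses the *center* voxel (bright, within the distance cut
  — default 20 µm).
* Depth of a patch/plane is the axial (z) distance below the top mask
  surface — per (y, x) column for patch centers, per stack for plane-wise
  summaries.

## Kymographs

A kymograph is a T × Z matrix of plane-averaged information-content gain of
a restored series over its input series. Each plane is divided into 2D tiles
(default 64×64; tests use 32×32 on small phantoms) and a tile contributes
`IIC(restored)/IIC(input)` if at least 5 % of its input voxels exceed the
frame-level Otsu threshold. This foreground-fraction rule replaces a
tile-mean criterion: with realistically sparse nuclear labeling, tile means
sit near background and a mean-above-Otsu rule excludes essentially every
tile, leaving the kymograph empty. Cells with no qualifying tile are missing
(NaN), never zero; marginals are NaN-aware means, so the count-weighted
means of both marginals equal the grand mean exactly.

## The synthetic phantom

The phantom emulates a nuclear-labeled embryo: a filled ellipsoid mask
(default semi-axes 28×60×60 µm on a 64×256×256 grid at 1×0.5×0.5 µm),
`n_nuclei` isotropic Gaussian blobs (default 300, radius 3 ± 0.5 µm, peak
amplitude 200 ± 15 % over a background of 10 counts) whose centers fall
uniformly in the mask interior at least one nucleus radius from the surface,
so ≥ 99 % of signal stays inside the mask. The paired degradation applies,
in order: plane-wise exponential attenuation of signal above background
(`exp(-d/ℓ)`, default ℓ = 50 µm, with d the plane's depth below the top mask
surface), per-plane 2D Gaussian blur with σ(d) = σ0 + slope·d (defaults
0.5 µm + 0.05 µm/µm — separable, fast, monotone in depth), an optional
integer chromatic translation (the degraded voxel `v` shows the processed
truth at `v + offset`, which is exactly the offset registration reports),
then Poisson shot noise followed by additive Gaussian read noise (sd 2
counts), clipped at zero. Shot noise precedes read noise because that is the
physical order in a camera; no claim is made that the real instrument's
noise follows this model.

Time-lapse sequences re-render the same nuclei after an isotropic Gaussian
random-walk step per frame (steps that would exit the interior are skipped
for that nucleus), with an independent noise stream per frame; frame 0
reproduces the static pipeline bit for bit.

What the phantom does *not* emulate: optical PSF physics and light-sheet
geometry, refractive-index effects, spatially varying labeling density,
autofluorescence, cell divisions and large-scale tissue flows. Passing tests
therefore demonstrate that the algorithms behave as specified on data with
depth-graded blur/attenuation/noise — not that any particular quality level
will be reached on a given microscope.

## Scales used by the test-suite and the verification script

The default phantom (64×256×256) drives the sampling/coverage checks. The
end-to-end restoration property is verified at desk scale: 48×192×192
phantoms, patches of 16×64×64 voxels (`(z, y, x)`; i.e. 64×64×16 in
rows×cols×planes), 12 patch pairs, base 8 channels, 30 epochs, three seeds
with a 2-of-3 majority rule — sizes chosen so a single-CPU run finishes in a
few minutes. Full-scale settings (128×128×32 patches, 100 epochs, batch 8)
remain the config defaults. The registration recovery check scans all 125
integer shifts within ±2 voxels (search box (2, 4, 4)) noise-free, and 100
random shifts at 10 % additive Gaussian noise.

## Known limitations

* The coverage statistic is a definition choice (fraction of foreground
  voxels under at least one patch); other stopping statistics would change
  when extraction halts but not what is extracted.
* Integer-voxel registration cannot correct subvoxel chromatic shifts.
* The numpy U-Net trains at CPU speed; full-scale training (thousands of
  128×128×32 patches, 100 epochs) is out of reach here and would be run on
  an accelerator-backed implementation of the same architecture.
* DCT-entropy gain rewards genuine structure but also responds to broadband
  noise; the foreground-fraction tile rule and patch selection mitigate,
  but gains on nearly empty regions are not meaningful.
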