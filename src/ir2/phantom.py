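"""Synthetic embryo phantoms: paired ground-truth/degraded volumes.

This module fabricates the kind of data the restoration pipeline consumes:
a clean "ground-truth" channel showing blob-like nuclear fluorescence inside
a smooth ellipsoidal embryo, and a co-registered "degraded" channel in which
image quality deteriorates with detection depth — growing blur, exponential
intensity attenuation, shot noise and camera read noise, plus an optional
small chromatic translation between the channels.

The forward model is deliberately simple (per-plane Gaussian blur whose
sigma grows linearly with plane depth, plane-wise exponential attenuation)
but reproduces the qualitative signature of deep-tissue light-sheet data:
information content and structural similarity of the degraded channel fall
off with depth while the ground truth stays sharp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidSpecError
from .volume import Volume, mask_top_plane, plane_detection_depth


@dataclass
class PhantomSpec:
    """Geometry and photometry of the synthetic embryo.

    Defaults describe a half-embryo field of view: a 64×256×256 voxel grid at
    1×0.5×0.5 µm spacing containing an ellipsoidal sample with a few hundred
    GFP-like nuclei of ~3 µm radius over a dim background.
    """

    grid_shape: tuple[int, int, int] = (64, 256, 256)
    voxel_spacing_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    embryo_semi_axes_um: tuple[float, float, float] = (28.0, 60.0, 60.0)
    n_nuclei: int = 300
    nucleus_radius_um: tuple[float, float] = (3.0, 0.5)  # mean, spread (sd)
    nucleus_intensity: float = 200.0
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(int(s) <= 0 for s in self.grid_shape):
            raise InvalidSpecError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise InvalidSpecError("voxel_spacing_um must be positive")
        if any(a <= 0 for a in self.embryo_semi_axes_um):
            raise InvalidSpecError("embryo_semi_axes_um must be positive")
        if self.n_nuclei < 0:
            raise InvalidSpecError(f"n_nuclei must be >= 0, got {self.n_nuclei}")
        if self.nucleus_radius_um[0] <= 0:
            raise InvalidSpecError("mean nucleus radius must be positive")
        if self.background_level < 0:
            raise InvalidSpecError("background_level must be >= 0")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)


@dataclass
class DegradationSpec:
    """Depth-dependent degradation applied to the ground-truth channel.

    ``blur_sigma0_um`` is the in-plane blur at the sample surface and
    ``blur_slope`` the extra sigma (µm) added per µm of plane depth.  Signal
    above background decays as ``exp(-depth / attenuation_length_um)``;
    ``math.inf`` disables attenuation.  ``poisson_scale`` is the number of
    photons represented by one count (0 disables shot noise).
    ``channel_offset_voxels`` is the translation registration should recover:
    the degraded channel at voxel ``v`` shows the (processed) ground truth at
    ``v + offset``.
    """

    blur_sigma0_um: float = 0.5
    blur_slope: float = 0.05
    attenuation_length_um: float = 50.0
    gaussian_read_noise_sd: float = 2.0
    poisson_scale: float = 1.0
    channel_offset_voxels: tuple[int, int, int] = (0, 0, 0)
    seed: int = 0

    def __post_init__(self):
        if self.attenuation_length_um <= 0 or math.isnan(self.attenuation_length_um):
            raise InvalidSpecError(
                f"attenuation_length_um must be > 0 (inf allowed), got "
                f"{self.attenuation_length_um}"
            )
        if self.blur_sigma0_um < 0 or self.blur_slope < 0:
            raise InvalidSpecError("blur parameters must be >= 0")
        if self.gaussian_read_noise_sd < 0 or self.poisson_scale < 0:
            raise InvalidSpecError("noise parameters must be >= 0")
        self.channel_offset_voxels = tuple(int(o) for o in self.channel_offset_voxels)


@dataclass
class PairedVolume:
    """Co-registered ground-truth/degraded channels with mask and depth map.

    ``depth_map`` is the Euclidean distance (µm) of each interior voxel from
    the mask surface, 0 outside; used for surface-proximity queries.
    """

    ground_truth: Volume
    degraded: Volume | None
    mask: np.ndarray
    depth_map: np.ndarray
    nuclei: "NucleusSet | None" = None

    @property
    def shape(self):
        return self.ground_truth.shape

    @property
    def spacing_um(self):
        return self.ground_truth.spacing_um


@dataclass
class NucleusSet:
    """Sampled nucleus parameters, kept so time-lapse frames can re-render."""

    centers_um: np.ndarray  # (n, 3) physical coordinates (z, y, x) in µm
    sigmas_um: np.ndarray  # (n,) isotropic Gaussian sigma in µm
    amplitudes: np.ndarray  # (n,) peak intensity above background


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    center = [(s - 1) / 2.0 for s in shape]
    axes = [
        np.arange(s) * sp - c * sp
        for s, sp, c in zip(shape, spec.voxel_spacing_um, center)
    ]
    zz = (axes[0] / spec.embryo_semi_axes_um[0]) ** 2
    yy = (axes[1] / spec.embryo_semi_axes_um[1]) ** 2
    xx = (axes[2] / spec.embryo_semi_axes_um[2]) ** 2
    return (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]) <= 1.0


def _sample_nuclei(spec: PhantomSpec, depth_map: np.ndarray,
                   rng: np.random.Generator) -> NucleusSet:
    """Draw nucleus centers uniformly inside the mask, away from the surface.

    Centers are constrained to lie at least one nucleus radius from the mask
    surface so that blob tails stay inside the sample.
    """
    mean_r, sd_r = spec.nucleus_radius_um
    sigmas = np.clip(rng.normal(mean_r, sd_r, spec.n_nuclei), 0.3 * mean_r, None) / 2.0
    amps = np.clip(
        rng.normal(spec.nucleus_intensity, 0.15 * spec.nucleus_intensity,
                   spec.n_nuclei),
        0.2 * spec.nucleus_intensity, None,
    )
    interior = np.argwhere(depth_map >= mean_r)
    if spec.n_nuclei > 0 and interior.shape[0] == 0:
        raise InvalidSpecError(
            "embryo mask too thin to place nuclei at the requested radius"
        )
    if spec.n_nuclei > 0:
        idx = rng.integers(0, interior.shape[0], spec.n_nuclei)
        centers_vox = interior[idx].astype(float)
        # jitter within the voxel so centers are not grid-locked
        centers_vox += rng.uniform(-0.5, 0.5, centers_vox.shape)
        centers_um = centers_vox * np.asarray(spec.voxel_spacing_um)
    else:
        centers_um = np.zeros((0, 3))
    return NucleusSet(centers_um=centers_um, sigmas_um=sigmas[: spec.n_nuclei],
                      amplitudes=amps[: spec.n_nuclei])


def _render(spec: PhantomSpec, mask: np.ndarray, nuclei: NucleusSet) -> np.ndarray:
    """Sum isotropic Gaussian blobs over the background level.

    Each blob is rendered only inside a ±4σ bounding box for speed.
    """
    spacing = np.asarray(spec.voxel_spacing_um)
    img = np.full(spec.grid_shape, float(spec.background_level), dtype=np.float64)
    for c_um, sig_um, amp in zip(nuclei.centers_um, nuclei.sigmas_um,
                                 nuclei.amplitudes):
        c_vox = c_um / spacing
        half = np.ceil(4.0 * sig_um / spacing).astype(int)
        lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
        hi = np.minimum(np.floor(c_vox).astype(int) + half + 1, spec.grid_shape)
        if np.any(lo >= hi):
            continue
        ax = [
            (np.arange(l, h) * sp - cu) ** 2
            for l, h, sp, cu in zip(lo, hi, spacing, c_um)
        ]
        r2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(
            -r2 / (2.0 * sig_um ** 2)
        )
    np.maximum(img, 0.0, out=img)
    return img


def generate_phantom(spec: PhantomSpec) -> PairedVolume:
    """Generate the clean channel: ellipsoid mask, depth map and nuclei.

    The degraded channel is left unset; apply :func:`degrade_volume` to fill
    it.  Identical spec (including seed) reproduces the volume bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec)
    if not mask.any():
        raise InvalidSpecError("embryo ellipsoid does not intersect the grid")
    depth_map = ndimage.distance_transform_edt(
        mask, sampling=spec.voxel_spacing_um
    )
    nuclei = _sample_nuclei(spec, depth_map, rng)
    gt = _render(spec, mask, nuclei)
    return PairedVolume(
        ground_truth=Volume(gt, spec.voxel_spacing_um, "ground_truth"),
        degraded=None,
        mask=mask,
        depth_map=depth_map,
        nuclei=nuclei,
    )


def _depth_varying_blur(img: np.ndarray, plane_depth_um: np.ndarray,
                        deg: DegradationSpec, spacing_um) -> np.ndarray:
    out = np.empty_like(img)
    for z in range(img.shape[0]):
        sigma_um = deg.blur_sigma0_um + deg.blur_slope * plane_depth_um[z]
        sigma_vox = (sigma_um / spacing_um[1], sigma_um / spacing_um[2])
        if sigma_um <= 0:
            out[z] = img[z]
        else:
            out[z] = ndimage.gaussian_filter(img[z], sigma_vox, mode="nearest")
    return out


def _translate(img: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift so that out[v] = img[v + offset] (edge replication at borders)."""
    if all(o == 0 for o in offset):
        return img
    return ndimage.shift(img, [-o for o in offset], order=0, mode="nearest")


def degrade_volume(pair: PairedVolume, deg: DegradationSpec) -> PairedVolume:
    """Fill the degraded channel from the ground truth.

    Pipeline: plane-wise exponential attenuation of the signal above
    background, depth-varying in-plane Gaussian blur, translation by the
    chromatic channel offset, then shot noise and additive read noise.
    Negative values are clipped to zero.
    """
    if pair.ground_truth is None:
        raise InvalidSpecError("pair has no ground-truth channel")
    rng = np.random.default_rng(deg.seed)
    spec_spacing = pair.spacing_um
    gt = pair.ground_truth.data.astype(np.float64)
    # median, not mean: faint blob tails leaking past the mask bias the mean
    bg = float(np.median(gt[~pair.mask])) if (~pair.mask).any() else 0.0

    plane_depth = plane_detection_depth(pair.mask, spec_spacing)
    if math.isinf(deg.attenuation_length_um):
        att = np.ones_like(plane_depth)
    else:
        att = np.exp(-plane_depth / deg.attenuation_length_um)
    img = bg + (gt - bg) * att[:, None, None]

    img = _depth_varying_blur(img, plane_depth, deg, spec_spacing)
    img = _translate(img, deg.channel_offset_voxels)

    if deg.poisson_scale > 0:
        img = rng.poisson(np.maximum(img, 0.0) * deg.poisson_scale) / deg.poisson_scale
    if deg.gaussian_read_noise_sd > 0:
        img = img + rng.normal(0.0, deg.gaussian_read_noise_sd, img.shape)
    img = np.maximum(img, 0.0)

    return replace(
        pair,
        degraded=Volume(img, spec_spacing, "degraded"),
    )


def generate_timelapse(spec: PhantomSpec, deg: DegradationSpec,
                       n_timepoints: int,
                       drift_um_per_step: float = 0.0) -> list[PairedVolume]:
    """Short synthetic time-lapse: nuclei random-walk, fresh noise per frame.

    Frame 0 equals ``degrade_volume(generate_phantom(spec), deg)``; at each
    subsequent step every nucleus center moves by an isotropic Gaussian step
    of sd ``drift_um_per_step`` per axis (clipped back inside the mask) and
    the degradation is re-applied with a per-frame noise stream derived from
    ``deg.seed``.
    """
    if n_timepoints < 1:
        raise InvalidSpecError(f"n_timepoints must be >= 1, got {n_timepoints}")
    base = generate_phantom(spec)
    drift_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    frames: list[PairedVolume] = []
    nuclei = base.nuclei
    mean_r = spec.nucleus_radius_um[0]
    interior = base.depth_map >= mean_r
    spacing = np.asarray(spec.voxel_spacing_um)
    for t in range(n_timepoints):
        if t > 0:
            step = drift_rng.normal(0.0, drift_um_per_step,
                                    nuclei.centers_um.shape)
            centers = nuclei.centers_um + step
            if centers.size:
                vox = np.clip(
                    np.round(centers / spacing).astype(int),
                    0, np.asarray(spec.grid_shape) - 1,
                )
                outside = ~interior[vox[:, 0], vox[:, 1], vox[:, 2]]
                centers[outside] = nuclei.centers_um[outside]
            nuclei = NucleusSet(centers, nuclei.sigmas_um, nuclei.amplitudes)
        gt = base.ground_truth.data if t == 0 else _render(spec, base.mask, nuclei)
        frame = PairedVolume(
            ground_truth=Volume(gt, spec.voxel_spacing_um, "ground_truth"),
            degraded=None,
            mask=base.mask,
            depth_map=base.depth_map,
            nuclei=nuclei,
        )
        frame_deg = deg if t == 0 else replace(
            deg, seed=int(np.random.SeedSequence([deg.seed, t]).generate_state(1)[0]
                          % (2 ** 31))
        )
        frames.append(degrade_volume(frame, frame_deg))
    return frames
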