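"""Image-quality metric suite for paired-volume restoration.

Four headline metrics quantify how close a (degraded or restored) image is
to its reference and how much spatial structure it carries:

* ``nrmse(x, y)``  — root-mean-square difference normalized by the mean of
  the reference: ``sqrt(<(x - y)^2>) / <y>``.
* ``pearson(x, y)`` — product-moment correlation of flattened intensities,
  evaluated on patches chosen to avoid dark regions.
* ``ssim(x, y)``   — structural similarity (product of luminance, contrast
  and structure terms over Gaussian-weighted local windows).
* ``information_content(patch)`` — Shannon entropy (natural log) of the
  normalized squared discrete-cosine-transform spectrum,
  ``IIC = -sum p_ij ln p_ij`` with ``p = F / sum F`` and
  ``F(i, j) = DCT(I)^2 / N^2``.  The ``N^2`` divisor cancels in ``p`` and is
  kept for fidelity to the definition.

``information_gain(a, b)`` is the IIC ratio; values above 1 mean image ``a``
resolves more structure than ``b`` in the same field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import ndimage
from skimage.metrics import structural_similarity as _sk_ssim

from .errors import (
    DegenerateInputError,
    DegenerateReferenceError,
    EmptySelectionError,
    InvalidConfigError,
)
from .sampling import admissible_center_bounds, otsu_threshold, patch_slices
from .volume import axial_depth_map


@dataclass
class SpectralEntropyConfig:
    """How the DCT-entropy information content is evaluated.

    ``mode="plane"`` (default) takes the 2D DCT of every z plane and averages
    the per-plane entropies, matching plane-wise depth profiles; ``"volume"``
    uses a single 3D DCT.  Both agree exactly on single-plane patches.
    """

    mode: str = "plane"

    def __post_init__(self):
        if self.mode not in ("plane", "volume"):
            raise InvalidConfigError(f"mode must be 'plane' or 'volume', got {self.mode!r}")


@dataclass
class QualityRecord:
    """Per-patch metric bundle."""

    patch_id: int
    center: tuple[int, int, int]
    depth_um: float
    nrmse: float
    pearson: float
    ssim: float
    iic_a: float
    iic_b: float
    gain: float


def nrmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error of ``x`` against reference ``y``, over mean(y)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidConfigError(f"shape mismatch: {x.shape} vs {y.shape}")
    my = y.mean()
    if my == 0:
        raise DegenerateReferenceError("reference image has zero mean")
    return float(np.sqrt(np.mean((x - y) ** 2)) / my)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of the flattened intensities."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise InvalidConfigError("shape mismatch")
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm * xm).sum() * (ym * ym).sum())
    if denom == 0:
        raise DegenerateInputError("constant input to Pearson correlation")
    return float((xm * ym).sum() / denom)


def ssim(x: np.ndarray, y: np.ndarray, window_sd: float = 1.5,
         k1: float = 0.01, k2: float = 0.03,
         data_range: float | None = None) -> float:
    """Mean structural similarity with Gaussian-weighted local windows.

    ``data_range`` defaults to the intensity span of the reference ``y``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidConfigError("shape mismatch")
    if data_range is None:
        data_range = float(y.max() - y.min())
        if data_range == 0:
            # constant reference: fall back to the pair's joint span so the
            # closed-form luminance comparison still applies
            data_range = float(max(x.max(), y.max()) - min(x.min(), y.min()))
            if data_range == 0:
                return 1.0
    if data_range <= 0:
        raise InvalidConfigError(f"data_range must be > 0, got {data_range}")

    def _one(a, b):
        return float(_sk_ssim(
            a, b, gaussian_weights=True, sigma=window_sd,
            use_sample_covariance=False, K1=k1, K2=k2, data_range=data_range,
        ))

    win = 2 * int(3.5 * window_sd + 0.5) + 1
    if x.ndim == 3 and x.shape[0] < win <= min(x.shape[1:]):
        # patch too thin axially for a 3D window: average per-plane 2D SSIM
        return float(np.mean([_one(x[z], y[z]) for z in range(x.shape[0])]))
    return _one(x, y)


def _plane_iic(plane: np.ndarray) -> float:
    coeffs = sp_fft.dctn(plane, type=2, norm="ortho")
    f = coeffs ** 2 / float(plane.size) ** 2
    total = f.sum()
    if total == 0:
        return 0.0
    p = f / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def information_content(patch: np.ndarray,
                        cfg: SpectralEntropyConfig | None = None) -> float:
    """DCT Shannon-entropy information content of a 2D or 3D patch."""
    if cfg is None:
        cfg = SpectralEntropyConfig()
    patch = np.asarray(patch, dtype=np.float64)
    if patch.size == 0:
        raise DegenerateInputError("empty patch")
    if patch.ndim == 2:
        return _plane_iic(patch)
    if patch.ndim != 3:
        raise InvalidConfigError(f"patch must be 2D or 3D, got ndim={patch.ndim}")
    if cfg.mode == "volume" and patch.shape[0] > 1:
        return _plane_iic(patch)  # dctn handles nD identically
    return float(np.mean([_plane_iic(patch[z]) for z in range(patch.shape[0])]))


def information_gain(a: np.ndarray, b: np.ndarray,
                     cfg: SpectralEntropyConfig | None = None) -> float:
    """IIC ratio of image ``a`` relative to reference image ``b``."""
    iic_b = information_content(b, cfg)
    if iic_b == 0:
        raise DegenerateReferenceError("reference image has zero information content")
    return information_content(a, cfg) / iic_b


def surface_distance_map(mask: np.ndarray, spacing_um) -> np.ndarray:
    """Euclidean distance (µm) of every voxel to the mask's edge shell.

    The edge is the mask minus its binary erosion; distances are computed
    with anisotropic voxel spacing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("mask is empty")
    edge = mask & ~ndimage.binary_erosion(mask)
    return ndimage.distance_transform_edt(~edge, sampling=spacing_um)


def surface_patch_selector(volume: np.ndarray, mask_threshold: float | None,
                           max_distance_um: float, patch_shape,
                           n: int, seed: int,
                           spacing_um=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Sample patch centers near the sample surface, avoiding dark regions.

    The sample mask is ``volume > mask_threshold`` (Otsu when ``None``); a
    center qualifies if it lies in the mask, its patch fits in the volume and
    its distance to the erosion-derived edge shell is at most
    ``max_distance_um``.  Returns up to ``n`` centers drawn without
    replacement with a fixed seed, as an ``(m, 3)`` integer array.
    """
    data = np.asarray(volume, dtype=np.float64)
    if mask_threshold is None:
        mask_threshold = otsu_threshold(data)
    mask = data > mask_threshold
    dist = surface_distance_map(mask, spacing_um)
    candidates = mask & (dist <= max_distance_um)
    bounds = admissible_center_bounds(data.shape, patch_shape)
    adm = np.zeros(data.shape, dtype=bool)
    adm[tuple(slice(lo, hi) for lo, hi in bounds)] = True
    candidates &= adm
    idx = np.argwhere(candidates)
    if idx.shape[0] == 0:
        raise EmptySelectionError(
            f"no foreground voxel within {max_distance_um} µm of the surface "
            f"admits a {tuple(patch_shape)} patch"
        )
    rng = np.random.default_rng(seed)
    take = min(n, idx.shape[0])
    sel = rng.choice(idx.shape[0], size=take, replace=False)
    return idx[sel]


def evaluate_patchwise(volumes: dict, centers, patch_shape,
                       cfg: SpectralEntropyConfig | None = None,
                       spacing_um=(1.0, 1.0, 1.0),
                       mask: np.ndarray | None = None,
                       n_depth_bins: int = 4):
    """Per-patch quality records plus depth-binned summary statistics.

    ``volumes`` maps roles to arrays and must contain ``degraded`` and
    ``truth``; an optional ``restored`` entry switches the comparison image.
    For each center, NRMSE/Pearson/SSIM compare the evaluated image (restored
    if present, else degraded) against the truth; the information-content
    gain is IIC(restored)/IIC(degraded) when restored is present, else
    IIC(truth)/IIC(degraded).  Patch depth is the axial distance of the
    center below the top mask surface in its (y, x) column.

    Returns ``(records, summary)`` where ``records`` is a DataFrame with one
    row per center and ``summary`` a dict with overall and depth-binned
    statistics per metric.
    """
    centers = np.asarray(centers)
    if centers.size == 0:
        raise EmptySelectionError("no evaluation centers supplied")
    if "degraded" not in volumes or "truth" not in volumes:
        raise InvalidConfigError("volumes must contain 'degraded' and 'truth'")
    deg = np.asarray(volumes["degraded"], dtype=np.float64)
    truth = np.asarray(volumes["truth"], dtype=np.float64)
    restored = volumes.get("restored")
    restored = None if restored is None else np.asarray(restored, dtype=np.float64)
    shapes = {deg.shape, truth.shape} | ({restored.shape} if restored is not None else set())
    if len(shapes) != 1:
        raise InvalidConfigError("volumes must be co-shaped")

    if mask is None:
        mask = truth > otsu_threshold(truth)
    depth = axial_depth_map(mask, spacing_um)

    records = []
    for i, c in enumerate(centers):
        c = tuple(int(v) for v in c)
        sl = patch_slices(c, patch_shape)
        t = truth[sl]
        d = deg[sl]
        a = restored[sl] if restored is not None else d
        iic_d = information_content(d, cfg)
        iic_a = information_content(a if restored is not None else t, cfg)
        records.append(QualityRecord(
            patch_id=i,
            center=c,
            depth_um=float(depth[c]),
            nrmse=nrmse(a, t),
            pearson=pearson(a, t),
            ssim=ssim(a, t),
            iic_a=iic_a,
            iic_b=iic_d,
            gain=iic_a / iic_d if iic_d > 0 else np.nan,
        ))
    df = pd.DataFrame([r.__dict__ for r in records])

    metric_cols = ["nrmse", "pearson", "ssim", "iic_a", "iic_b", "gain"]
    overall = df[metric_cols].agg(["mean", "std", "min",
                                   lambda s: s.quantile(0.25),
                                   "median",
                                   lambda s: s.quantile(0.75),
                                   "max"])
    overall.index = ["mean", "sd", "min", "q25", "median", "q75", "max"]
    edges = np.linspace(df.depth_um.min(), df.depth_um.max() + 1e-9,
                        n_depth_bins + 1)
    df["depth_bin"] = pd.cut(df.depth_um, edges, include_lowest=True)
    by_depth = df.groupby("depth_bin", observed=True)[metric_cols].agg(
        ["mean", "std", "count"])
    summary = {"overall": overall, "by_depth": by_depth}
    return df, summary
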