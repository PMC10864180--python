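"""Depth x time restoration-quality analysis for time-lapse volumes.

The central object is a kymograph: a T x Z matrix of plane-averaged
information-content gain of a restored series relative to its input series,
with depth- and time-averaged marginal profiles.  Gains are averaged over
bright 2D tiles of each plane (tiles whose mean exceeds the frame's Otsu
threshold) so dark borders do not dilute the statistic; planes with no
qualifying tile are marked missing (NaN), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateInputError,
    EmptySelectionError,
    InvalidConfigError,
)
from .metrics import SpectralEntropyConfig, information_content
from .restoration import normalize_percentile
from .sampling import otsu_threshold

#: in-plane tile used to aggregate per-plane gain
DEFAULT_TILE = (64, 64)


@dataclass
class Kymograph:
    """Time x depth matrix of plane-averaged information-content gain."""

    matrix: np.ndarray  # (T, Z), NaN where no tile qualified
    time_axis: np.ndarray
    depth_axis: np.ndarray

    @property
    def depth_marginal(self) -> np.ndarray:
        """Time-averaged gain per depth (NaN-aware)."""
        return _nanmean_quiet(self.matrix, axis=0)

    @property
    def time_marginal(self) -> np.ndarray:
        """Depth-averaged gain per time point (NaN-aware)."""
        return _nanmean_quiet(self.matrix, axis=1)


def _nanmean_quiet(a, axis):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)


def _plane_tiles(plane: np.ndarray, tile_shape):
    ty, tx = tile_shape
    ny, nx = plane.shape[0] // ty, plane.shape[1] // tx
    if ny == 0 or nx == 0:
        # plane smaller than one tile: use it whole
        yield plane
        return
    for iy in range(ny):
        for ix in range(nx):
            yield plane[iy * ty:(iy + 1) * ty, ix * tx:(ix + 1) * tx]


def ic_gain_kymograph(input_series, restored_series,
                      tile_shape=DEFAULT_TILE,
                      cfg: SpectralEntropyConfig | None = None,
                      spacing_um=(1.0, 1.0, 1.0),
                      time_axis=None,
                      min_foreground_fraction: float = 0.05) -> Kymograph:
    """Plane-averaged information-content gain for every (time, depth) cell.

    ``input_series`` and ``restored_series`` are sequences of co-shaped 3D
    arrays.  For each frame, non-dark tiles of each z plane contribute
    ``IIC(restored tile) / IIC(input tile)``; the cell value is their mean.
    A tile is non-dark when at least ``min_foreground_fraction`` of its
    voxels exceed the frame-level Otsu threshold, so gain is measured where
    there is structure to restore rather than on empty background.
    """
    if len(input_series) != len(restored_series):
        raise AlignmentError(
            f"series lengths differ: {len(input_series)} vs {len(restored_series)}"
        )
    if len(input_series) == 0:
        raise AlignmentError("empty series")
    shape = np.asarray(input_series[0]).shape
    n_t, n_z = len(input_series), shape[0]
    matrix = np.full((n_t, n_z), np.nan)
    for t, (inp, res) in enumerate(zip(input_series, restored_series)):
        inp = np.asarray(inp, dtype=np.float64)
        res = np.asarray(res, dtype=np.float64)
        if inp.shape != shape or res.shape != shape:
            raise AlignmentError(f"frame {t} shape mismatch")
        try:
            thr = otsu_threshold(inp)
        except DegenerateInputError:
            continue
        for z in range(n_z):
            gains = []
            for tile_i, tile_r in zip(_plane_tiles(inp[z], tile_shape),
                                      _plane_tiles(res[z], tile_shape)):
                if (tile_i > thr).mean() < min_foreground_fraction:
                    continue
                iic_i = information_content(tile_i, cfg)
                if iic_i == 0:
                    continue
                gains.append(information_content(tile_r, cfg) / iic_i)
            if gains:
                matrix[t, z] = float(np.mean(gains))
    time_ax = (np.arange(n_t, dtype=float) if time_axis is None
               else np.asarray(time_axis, dtype=float))
    depth_ax = np.arange(n_z, dtype=float) * float(spacing_um[0])
    return Kymograph(matrix=matrix, time_axis=time_ax, depth_axis=depth_ax)


def kymograph_marginals(k: Kymograph):
    """(depth_marginal, time_marginal): NaN-aware means along each axis."""
    if k.matrix.size == 0:
        raise DegenerateInputError("empty kymograph")
    return k.depth_marginal, k.time_marginal


def normalized_difference_map(a: np.ndarray, b: np.ndarray,
                              percentiles=(0.3, 99.9)) -> np.ndarray:
    """|a' - b'| after per-image percentile normalization.

    Each image is independently rescaled by its own (0.3, 99.9) percentiles,
    giving both an identical dynamic range, then the absolute difference is
    returned.  Global intensity scale differences cancel exactly.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidConfigError("shape mismatch")
    a_n, _, _ = normalize_percentile(a, *percentiles)
    b_n, _, _ = normalize_percentile(b, *percentiles)
    return np.abs(a_n - b_n)


def select_showcase_patches(records, gain_cut: float = 1.2, n: int = 6,
                            seed: int = 0) -> list[int]:
    """Uniformly sample patch ids whose information-content gain beats a cut.

    ``records`` is any sequence with ``gain`` and ``patch_id`` attributes (or
    a DataFrame with those columns).  The default cut of 1.2 selects patches
    with a clear restoration benefit.
    """
    if hasattr(records, "itertuples"):
        items = [(int(r.patch_id), float(r.gain)) for r in records.itertuples()]
    else:
        items = [(int(r.patch_id), float(r.gain)) for r in records]
    if not items:
        raise EmptySelectionError("no records supplied")
    eligible = [pid for pid, g in items if g > gain_cut]
    if not eligible:
        raise EmptySelectionError(f"no record has gain > {gain_cut}")
    rng = np.random.default_rng(seed)
    take = min(n, len(eligible))
    picks = rng.choice(len(eligible), size=take, replace=False)
    return [eligible[i] for i in sorted(picks)]
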