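"""Integer-voxel patch registration by exhaustive normalized cross-correlation.

Residual chromatic aberration between the degraded and ground-truth channels
shows up as a small, locally constant translation.  Each patch pair is
registered independently by scanning every integer offset ``(dz, dy, dx)``
inside a search box and maximizing

    C(dz, dy, dx) = R(I(v), GT(v + d))

where ``R`` is the zero-mean, unit-variance (Pearson-style) correlation over
the overlapping region only — no zero padding, so border artifacts cannot
fabricate maxima.  Ties are broken toward the smallest offset norm, then
lexicographically, making the result platform-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GeometryError
from .sampling import PatchPair, patch_slices

#: default search radius (z, y, x) in voxels
DEFAULT_SEARCH_RADIUS = (2, 10, 10)


@dataclass(frozen=True)
class TranslationOffset:
    """Integer translation (z, y, x) with its correlation score."""

    dz: int
    dy: int
    dx: int
    score: float

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.dz, self.dy, self.dx)


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean, unit-variance correlation of two same-shape patches."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    am = a - a.mean()
    bm = b - b.mean()
    denom = np.sqrt((am * am).sum() * (bm * bm).sum())
    if denom == 0:
        raise DegenerateInputError("zero-variance input to cross-correlation")
    return float((am * bm).sum() / denom)


def _overlap_slices(shape, offset):
    """Slices of a and b so that a-index v pairs with b-index v + offset."""
    sl_a, sl_b = [], []
    for s, d in zip(shape, offset):
        lo_a = max(0, -d)
        hi_a = s - max(0, d)
        if hi_a <= lo_a:
            return None, None
        sl_a.append(slice(lo_a, hi_a))
        sl_b.append(slice(lo_a + d, hi_a + d))
    return tuple(sl_a), tuple(sl_b)


def register_patch_pair(input_patch: np.ndarray, truth_patch: np.ndarray,
                        search_radius=DEFAULT_SEARCH_RADIUS) -> TranslationOffset:
    """Exhaustive argmax of the correlation functional over the search box.

    Offsets whose overlap has zero variance in either patch score ``-inf``
    and can never win; if every offset is degenerate the input itself is
    degenerate and an error is raised.
    """
    a = np.asarray(input_patch, dtype=np.float64)
    b = np.asarray(truth_patch, dtype=np.float64)
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    radius = tuple(int(r) for r in search_radius)
    if any(r < 0 for r in radius):
        raise GeometryError("search radius must be non-negative")
    if any(s <= 2 * r for s, r in zip(a.shape, radius)):
        raise GeometryError(
            f"patch shape {a.shape} must exceed twice the radius {radius}"
        )

    best = None  # (score, norm2, offset)
    for dz in range(-radius[0], radius[0] + 1):
        for dy in range(-radius[1], radius[1] + 1):
            for dx in range(-radius[2], radius[2] + 1):
                sl_a, sl_b = _overlap_slices(a.shape, (dz, dy, dx))
                if sl_a is None:
                    continue
                aa = a[sl_a]
                bb = b[sl_b]
                am = aa - aa.mean()
                bm = bb - bb.mean()
                denom = np.sqrt((am * am).sum() * (bm * bm).sum())
                if denom == 0:
                    continue
                score = float((am * bm).sum() / denom)
                key = (-score, dz * dz + dy * dy + dx * dx, (dz, dy, dx))
                if best is None or key < best[0]:
                    best = (key, TranslationOffset(dz, dy, dx, score))
    if best is None:
        raise DegenerateInputError(
            "all offsets degenerate: patches have no variance"
        )
    return best[1]


def align_pair(pair: PatchPair, offset: TranslationOffset,
               truth_volume: np.ndarray | None = None) -> PatchPair:
    """Resample the ground-truth block at the registered offset.

    With the source volume available the block is re-extracted at
    ``center + offset`` (exact); otherwise the existing block is shifted with
    edge replication.  The offset is recorded on the returned pair.
    """
    d = offset.as_tuple()
    if all(o == 0 for o in d):
        return replace(pair, registration_offset=(0, 0, 0))
    shape = pair.truth_patch.shape
    if truth_volume is not None:
        center = tuple(int(c) + int(o) for c, o in zip(pair.center, d))
        sl = patch_slices(center, shape)
        for s, dim in zip(sl, truth_volume.shape):
            if s.start < 0 or s.stop > dim:
                raise GeometryError(
                    f"offset {d} pushes patch at {pair.center} outside the volume"
                )
        truth = truth_volume[sl].copy()
    else:
        # truth'(v) = truth(v + d): shift content by -d, replicating edges
        truth = ndimage.shift(np.asarray(pair.truth_patch, dtype=np.float64),
                              [-o for o in d], order=0, mode="nearest")
    return replace(pair, truth_patch=truth, registration_offset=d)


def register_pairs(pairs: list[PatchPair],
                   search_radius=DEFAULT_SEARCH_RADIUS,
                   truth_volume: np.ndarray | None = None) -> list[PatchPair]:
    """Register and align every pair; convenience wrapper for the pipeline."""
    out = []
    for p in pairs:
        off = register_patch_pair(p.degraded_patch, p.truth_patch, search_radius)
        out.append(align_pair(p, off, truth_volume))
    return out
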