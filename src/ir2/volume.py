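"""Core volumetric container and depth helpers.

A :class:`Volume` is a single-channel 3D intensity grid in plane-major
``(z, y, x)`` order with per-axis voxel spacing in micrometres and a named
role in the restoration workflow (``degraded``, ``ground_truth`` or
``restored``).  All coordinates throughout the package are 0-based voxel
indices in this axis order; physical units enter only through the spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidSpecError

#: Roles a channel can play in the paired-volume workflow.
VALID_ROLES = ("degraded", "ground_truth", "restored")


@dataclass
class Volume:
    """3D intensity grid with voxel spacing and channel role.

    Parameters
    ----------
    data:
        Array of shape ``(z, y, x)``.  Integer data is promoted to float32.
    spacing_um:
        Voxel spacing per axis ``(dz, dy, dx)`` in micrometres.
    role:
        One of :data:`VALID_ROLES`.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    role: str = "degraded"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise InvalidSpecError(
                f"Volume data must be 2D or 3D, got ndim={self.data.ndim}"
            )
        if np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.float32)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise InvalidSpecError(
                f"spacing_um must be three positive values, got {self.spacing_um}"
            )
        if self.role not in VALID_ROLES:
            raise InvalidSpecError(
                f"role must be one of {VALID_ROLES}, got {self.role!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, role: str | None = None) -> "Volume":
        """New Volume sharing spacing, with replaced data (and optional role)."""
        return replace(self, data=data, role=role if role is not None else self.role)


def mask_top_plane(mask: np.ndarray) -> int:
    """Index of the shallowest z plane intersecting the sample mask."""
    occupied = np.flatnonzero(mask.any(axis=(1, 2)))
    if occupied.size == 0:
        raise InvalidSpecError("mask is empty")
    return int(occupied[0])


def plane_detection_depth(mask: np.ndarray, spacing_um) -> np.ndarray:
    """Detection depth of each z plane below the mask's top surface, in µm.

    Planes above the mask get depth 0.  This is the per-plane depth used for
    depth-resolved summaries (depth of a plane = axial distance travelled
    into the sample by the detection path).
    """
    z_top = mask_top_plane(mask)
    z = np.arange(mask.shape[0])
    return np.maximum(0, z - z_top) * float(spacing_um[0])


def axial_depth_map(mask: np.ndarray, spacing_um) -> np.ndarray:
    """Per-voxel axial depth below the first masked plane of each (y, x) column.

    Columns that never intersect the mask carry 0 everywhere.  Values are in
    micrometres and non-negative; voxels above their column's surface are 0.
    """
    any_col = mask.any(axis=0)
    # argmax on a boolean column returns the first True; guard empty columns
    z_top = np.where(any_col, mask.argmax(axis=0), mask.shape[0])
    z = np.arange(mask.shape[0])[:, None, None]
    depth = (z - z_top[None]) * float(spacing_um[0])
    depth = np.maximum(depth, 0.0)
    depth[:, ~any_col] = 0.0
    return depth
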