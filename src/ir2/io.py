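"""Volume, patch and report I/O.

Volumes travel as multi-page TIFF stacks (plane-major, one z plane per
page); patch sets as a pair of stacked TIFF archives plus a CSV manifest;
configurations as YAML; summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError
from .sampling import PatchPair
from .volume import Volume


def read_volume(path, spacing_um=(1.0, 1.0, 1.0), role: str = "degraded") -> Volume:
    """Read a multi-page TIFF as a plane-major (z, y, x) volume.

    2D files become single-plane volumes; integer data is promoted to float
    for computation.  Spacing is taken from the caller (config), since TIFF
    resolution tags rarely carry trustworthy z spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                bad = [i for i, p in enumerate(tf.pages)
                       if p.shape != tf.pages[0].shape]
                raise FormatError(
                    f"{path}: page {bad[0]} shape differs from page 0"
                )
            data = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises various types on corrupt files
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2D/3D data, got shape {data.shape}")
    return Volume(data, spacing_um, role)


def write_volume(vol, path, dtype=None) -> Path:
    """Write a Volume (or bare array) as a plane-major multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if data.ndim == 2:
        data = data[np.newaxis]
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def write_mask(mask: np.ndarray, path) -> Path:
    """Binary mask as an 8-bit TIFF (255 inside)."""
    return write_volume((np.asarray(mask, dtype=bool) * np.uint8(255)), path,
                        dtype=np.uint8)


def write_patches(pairs: list[PatchPair], outdir) -> Path:
    """Patch pairs as two stacked TIFF archives plus a CSV manifest.

    The manifest carries one row per patch: center coordinates, the
    foreground flag and the registration offset.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    deg = np.stack([np.asarray(p.degraded_patch, dtype=np.float32) for p in pairs])
    tru = np.stack([np.asarray(p.truth_patch, dtype=np.float32) for p in pairs])
    tifffile.imwrite(outdir / "degraded_patches.tif", deg,
                     photometric="minisblack")
    tifffile.imwrite(outdir / "truth_patches.tif", tru,
                     photometric="minisblack")
    rows = [
        {
            "patch_id": i,
            "center_z": p.center[0], "center_y": p.center[1],
            "center_x": p.center[2],
            "is_foreground_center": p.is_foreground_center,
            "offset_z": p.registration_offset[0],
            "offset_y": p.registration_offset[1],
            "offset_x": p.registration_offset[2],
        }
        for i, p in enumerate(pairs)
    ]
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    return outdir


def read_patches(outdir) -> list[PatchPair]:
    """Inverse of :func:`write_patches`."""
    outdir = Path(outdir)
    deg = tifffile.imread(outdir / "degraded_patches.tif")
    tru = tifffile.imread(outdir / "truth_patches.tif")
    manifest = pd.read_csv(outdir / "manifest.csv")
    pairs = []
    for _, row in manifest.iterrows():
        i = int(row.patch_id)
        pairs.append(PatchPair(
            degraded_patch=deg[i],
            truth_patch=tru[i],
            center=(int(row.center_z), int(row.center_y), int(row.center_x)),
            is_foreground_center=bool(row.is_foreground_center),
            registration_offset=(int(row.offset_z), int(row.offset_y),
                                 int(row.offset_x)),
        ))
    return pairs


def write_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default))
    return path
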