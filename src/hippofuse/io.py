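"""Volume I/O (NIfTI-1) and grid canonicalization.

Coordinate convention: voxel indices are 0-based and world coordinates are
``origin + index * spacing``.  Segmentations are assumed axis-aligned; no
orientation or affine resampling is performed (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class VolumeGrid:
    """A 3-D array with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))


def read_mask_volume(path: str | Path, mask_mode: bool = True) -> VolumeGrid:
    """Read a NIfTI volume; in mask mode values must lie in [0, 1].

    Raises a ``ValueError`` naming the file for unreadable input, an empty
    mask, or (in mask mode) out-of-range values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending file
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    if mask_mode and (data.min() < 0 or data.max() > 1):
        raise ValueError(f"{path}: non-binary data in mask mode, value range "
                         f"[{data.min():g}, {data.max():g}] outside [0, 1]")
    if not np.any(data):
        raise ValueError(f"{path}: empty mask (all zeros)")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeGrid(data=data, spacing_mm=spacing, origin_mm=origin)


def write_mask_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a NIfTI-1 file with spacing encoded in the affine and header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def crop_pad_to_grid(volume: VolumeGrid, target_shape) -> VolumeGrid:
    """Center the foreground bounding box in a zero-padded target grid.

    Foreground voxel count and spacing are preserved; when a margin is odd
    the extra voxel goes to the high-index side.  The origin is shifted so
    world coordinates of the foreground are unchanged.
    """
    target_shape = tuple(int(t) for t in target_shape)
    data = volume.data
    nz = np.nonzero(data)
    if len(nz[0]) == 0:
        raise ValueError("cannot crop an empty volume")
    lo = [int(a.min()) for a in nz]
    hi = [int(a.max()) + 1 for a in nz]
    size = [h - l for l, h in zip(lo, hi)]
    if any(s > t for s, t in zip(size, target_shape)):
        raise ValueError(f"foreground of size {tuple(size)} does not fit in "
                         f"target grid {target_shape}")
    out = np.zeros(target_shape, dtype=data.dtype)
    starts = [(t - s) // 2 for s, t in zip(size, target_shape)]
    out[tuple(slice(st, st + s) for st, s in zip(starts, size))] = \
        data[tuple(slice(l, h) for l, h in zip(lo, hi))]
    origin = tuple(o + (l - st) * sp for o, l, st, sp in
                   zip(volume.origin_mm, lo, starts, volume.spacing_mm))
    return VolumeGrid(data=out, spacing_mm=volume.spacing_mm, origin_mm=origin)


def write_mesh(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> None:
    """Export a triangle mesh as ascii PLY or OFF (by file extension)."""
    import trimesh

    path = Path(path)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if path.suffix.lower() == ".ply":
        data = mesh.export(file_type="ply", encoding="ascii")
    elif path.suffix.lower() == ".off":
        data = mesh.export(file_type="off")
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
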