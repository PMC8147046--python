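"""Synthetic hippocampus-like paired binary volumes with two class signals.

Each subject is a pair of closed genus-0 shapes (left/right) built from an
ellipsoid template whose boundary radius is modulated by a smooth field of
Gaussian bumps on the sphere of directions.  The AD class differs from CN
in (a) a global signal — semi-axes shrunk by an atrophy factor — and (b) a
local surface-texture signal — a different bump density.  These two
independent signals make shape-only, visual-only and fused classifiers
separably testable.

The generator emulates the *structure* of segmented hippocampus data
(paired masks, a binary class label, per-subject anatomical variation); it
does not attempt realistic MRI intensities or atlas-based anatomy.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import VolumeGrid, read_mask_volume, write_mask_volume

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class Bump:
    """One Gaussian bump on the direction sphere."""

    direction: tuple[float, float, float]  # unit vector
    amplitude_mm: float
    width_rad: float = 0.35


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    ``atrophy_factor`` multiplies the AD-class semi-axes (global signal);
    ``bump_count_cn``/``bump_count_ad`` set the per-class surface-bump
    density (local signal); ``jitter_sd`` is the per-subject standard
    deviation (mm) of random semi-axis variation.
    """

    n_per_class: int = 100
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    base_semi_axes_mm: tuple[float, float, float] = (12.0, 8.0, 6.0)
    atrophy_factor: float = 0.85
    bump_amplitude_mm: float = 0.9
    bump_count_cn: int = 4
    bump_count_ad: int = 12
    bump_width_rad: float = 0.35
    jitter_sd: float = 0.3
    intensity: str = "binary"  # or "smooth"
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        self.base_semi_axes_mm = tuple(float(a) for a in self.base_semi_axes_mm)
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if not (0 < self.atrophy_factor <= 1):
            raise ValueError("atrophy_factor must be in (0, 1]")
        if self.bump_amplitude_mm < 0 or self.jitter_sd < 0:
            raise ValueError("bump_amplitude_mm and jitter_sd must be nonnegative")
        if min(self.bump_count_cn, self.bump_count_ad) < 0:
            raise ValueError("bump counts must be nonnegative")
        if self.intensity not in ("binary", "smooth"):
            raise ValueError(f"unknown intensity mode {self.intensity!r}")


@dataclass
class LabeledVolumePair:
    """One subject: left/right volumes on the same grid plus an AD/CN label."""

    subject_id: str
    left: VolumeGrid
    right: VolumeGrid
    label: str

    def __post_init__(self):
        if self.label not in ("AD", "CN"):
            raise ValueError(f"label must be 'AD' or 'CN', got {self.label!r}")
        if self.left.data.shape != self.right.data.shape:
            raise ValueError("left and right grids differ in shape")
        if self.left.spacing_mm != self.right.spacing_mm:
            raise ValueError("left and right grids differ in spacing")


def sample_bumps(rng: np.random.Generator, count: int, amplitude_mm: float,
                 width_rad: float = 0.35) -> list[Bump]:
    """Draw ``count`` bumps with uniformly random directions on the sphere."""
    bumps = []
    for _ in range(count):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        bumps.append(Bump(tuple(v), amplitude_mm, width_rad))
    return bumps


def _radial_surface(dirs: np.ndarray, semi_axes, bumps) -> np.ndarray:
    """Surface radius (mm) along unit directions: ellipsoid + bump field."""
    a = np.asarray(semi_axes, dtype=np.float64)
    r_ell = 1.0 / np.sqrt(np.sum((dirs / a) ** 2, axis=-1))
    r = r_ell
    for b in bumps:
        cosang = np.clip(dirs @ np.asarray(b.direction), -1.0, 1.0)
        theta = np.arccos(cosang)
        r = r + b.amplitude_mm * np.exp(-(theta ** 2) / (2 * b.width_rad ** 2))
    return r


def make_hippocampus_mask(semi_axes_mm, bumps, grid_shape, spacing,
                          margin: int = 2) -> np.ndarray:
    """Voxelize an ellipsoid with a smooth radial bump field.

    The shape is centered on the grid and thresholded at the implicit
    surface ``|x| = r(x/|x|)`` evaluated at voxel centers.  Raises if the
    shape cannot keep a ``margin``-voxel clearance from every grid face, or
    if the result is not a single 6-connected component.
    """
    semi_axes_mm = np.asarray(semi_axes_mm, dtype=np.float64)
    grid_shape = tuple(int(g) for g in grid_shape)
    spacing = np.asarray(spacing, dtype=np.float64)
    bumps = list(bumps or [])
    if np.any(semi_axes_mm <= 0):
        raise ValueError(f"semi-axes must be positive, got {tuple(semi_axes_mm)}")
    center = (np.asarray(grid_shape) - 1) / 2.0
    axes = [(np.arange(n) - c) * s for n, c, s in zip(grid_shape, center, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)
    rho = np.linalg.norm(pts, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(rho[..., None] > 0, pts / np.maximum(rho, 1e-30)[..., None],
                        [1.0, 0.0, 0.0])
    r_surf = _radial_surface(dirs, semi_axes_mm, bumps)
    mask = (rho <= r_surf).astype(np.uint8)
    border = np.ones(grid_shape, dtype=bool)
    border[margin:-margin, margin:-margin, margin:-margin] = False
    if np.any(mask[border]):
        need = int(np.ceil(2 * (float(r_surf.max()) / spacing.min() + margin + 1)))
        raise ValueError(
            f"shape exceeds grid {grid_shape} with a {margin}-voxel margin; "
            f"needs a grid of at least {need}^3 voxels at this spacing")
    n_comp = ndimage.label(mask, structure=_SIX_CONN)[1]
    if n_comp != 1:
        raise ValueError(f"mask is not a single 6-connected component ({n_comp} found)")
    return mask


def _fill_intensity(mask: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binary":
        return mask.astype(np.float32)
    dist = ndimage.distance_transform_edt(mask)
    top = dist.max()
    return (dist / top).astype(np.float32) if top > 0 else mask.astype(np.float32)


def generate_dataset(config: SyntheticConfig) -> list[LabeledVolumePair]:
    """Generate ``2 * n_per_class`` subjects; fully determined by the seed.

    Per subject and side, semi-axes are jittered by N(0, jitter_sd) mm and
    bump directions redrawn; the right side is mirrored along the first
    axis.  AD subjects use atrophy-scaled semi-axes and the AD bump count.
    """
    rng = np.random.default_rng(config.seed)
    base = np.asarray(config.base_semi_axes_mm)
    class_params = {
        "CN": (base, config.bump_count_cn),
        "AD": (base * config.atrophy_factor, config.bump_count_ad),
    }
    pairs = []
    sid = 0
    for label in ("CN", "AD"):
        axes0, n_bumps = class_params[label]
        for _ in range(config.n_per_class):
            sides = {}
            for side in ("L", "R"):
                axes = axes0 + rng.normal(0.0, config.jitter_sd, size=3)
                bumps = sample_bumps(rng, n_bumps, config.bump_amplitude_mm,
                                     config.bump_width_rad)
                mask = make_hippocampus_mask(axes, bumps, config.grid_shape,
                                             config.voxel_spacing_mm)
                if side == "R":
                    mask = mask[::-1].copy()
                sides[side] = VolumeGrid(_fill_intensity(mask, config.intensity),
                                         config.voxel_spacing_mm)
            pairs.append(LabeledVolumePair(subject_id=f"sub-{sid:04d}",
                                           left=sides["L"], right=sides["R"],
                                           label=label))
            sid += 1
    return pairs


def save_dataset(pairs: list[LabeledVolumePair], out_dir: str | Path,
                 config: SyntheticConfig | None = None) -> None:
    """Write per-subject NIfTI files plus a participants.csv manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "participants.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label"])
        for p in pairs:
            write_mask_volume(p.left, out_dir / f"{p.subject_id}_L.nii.gz")
            write_mask_volume(p.right, out_dir / f"{p.subject_id}_R.nii.gz")
            writer.writerow([p.subject_id, p.label])
    if config is not None:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(config).items()}
        (out_dir / "config.json").write_text(json.dumps(cfg, indent=2))


def load_dataset(data_dir: str | Path) -> list[LabeledVolumePair]:
    data_dir = Path(data_dir)
    manifest = data_dir / "participants.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no participants.csv in {data_dir}")
    pairs = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["subject_id"]
            pairs.append(LabeledVolumePair(
                subject_id=sid,
                left=read_mask_volume(data_dir / f"{sid}_L.nii.gz", mask_mode=False),
                right=read_mask_volume(data_dir / f"{sid}_R.nii.gz", mask_mode=False),
                label=row["label"]))
    return pairs
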