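"""Preprocessing chain and coarse-stage resolution changes.

The chain mirrors standard CT preparation for the surface-to-volume task:
resampling to a common voxel spacing (default 3 x 3 x 1.56 mm), integer-voxel
centering on the body's center of mass, symmetric crop/zero-pad to a fixed
grid, dataset-wide min/max normalization to [0, 1], and a seeded paired
augmentation (one shared shear-rotate-scale affine applied to both the volume
and its surface). The coarse cycle stage additionally consumes factor-2
trilinear down-sampled grids, and its output is trilinearly up-sampled back.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import SurfaceMatrix, VolumeGrid

__all__ = [
    "NormalizationRecord",
    "AugmentationPolicy",
    "resample",
    "center_by_mass",
    "crop_or_pad",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
    "augment_pair",
    "downsample_half",
    "upsample_to",
]

AIR_HU = -1000.0


@dataclasses.dataclass
class NormalizationRecord:
    """Dataset-wide affine intensity map x -> (x - min) / (max - min)."""

    global_min: float
    global_max: float
    dataset_id: str = ""

    def __post_init__(self):
        if not self.global_max > self.global_min:
            raise ValueError("global_max must exceed global_min")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationRecord":
        return cls(**d)


@dataclasses.dataclass
class AugmentationPolicy:
    """Random paired affine augmentation (drawn once per pair).

    Magnitudes are drawn uniformly in [0, max] per axis with a random sign;
    the same affine is applied to both members of a (volume, surface) pair.
    """

    probability: float = 0.5
    shear_max: float = 0.1
    rotation_max: float = 10.0  # degrees
    scale_max: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if min(self.shear_max, self.rotation_max, self.scale_max) < 0:
            raise ValueError("augmentation maxima must be non-negative")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _resize_trilinear(data: np.ndarray, out_shape, in_per_out=None) -> np.ndarray:
    """Trilinear resize aligning voxel (block) centers."""
    out_shape = tuple(int(s) for s in out_shape)
    if tuple(data.shape) == out_shape:
        return data.astype(np.float32, copy=True)
    if in_per_out is None:
        in_per_out = [i / o for i, o in zip(data.shape, out_shape)]
    coords = np.meshgrid(
        *[
            (np.arange(o, dtype=np.float64) + 0.5) * f - 0.5
            for o, f in zip(out_shape, in_per_out)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        data.astype(np.float32), coords, order=1, mode="nearest"
    ).astype(np.float32)


def resample(volume: VolumeGrid, target_spacing) -> VolumeGrid:
    """Trilinear resample onto a grid covering the same physical extent."""
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    out_shape = tuple(
        max(1, int(round(n * s_in / s_out)))
        for n, s_in, s_out in zip(volume.shape, volume.spacing, target_spacing)
    )
    factors = [s_out / s_in for s_in, s_out in zip(volume.spacing, target_spacing)]
    data = _resize_trilinear(volume.intensities, out_shape, in_per_out=factors)
    return dataclasses.replace(volume, intensities=data, spacing=target_spacing)


def mass_center_shift(volume: VolumeGrid, body_threshold: float = -400.0) -> tuple:
    """Integer-voxel translation that centers the body mask's center of mass."""
    mask = volume.intensities >= body_threshold
    if not mask.any():
        raise ValueError("empty body mask: cannot center by mass")
    com = ndimage.center_of_mass(mask)
    center = [(n - 1) / 2.0 for n in volume.shape]
    return tuple(int(round(c - m)) for c, m in zip(center, com))


def apply_shift(volume: VolumeGrid, shift, fill_value: float = AIR_HU) -> VolumeGrid:
    """Translate by integer voxels, filling vacated voxels."""
    out = np.full(volume.shape, fill_value, dtype=np.float32)
    src, dst = [], []
    for n, sh in zip(volume.shape, shift):
        sh = int(sh)
        src.append(slice(max(0, -sh), min(n, n - sh)))
        dst.append(slice(max(0, sh), min(n, n + sh)))
    out[tuple(dst)] = volume.intensities[tuple(src)]
    return volume.with_intensities(out)


def center_by_mass(
    volume: VolumeGrid, body_threshold: float = -400.0, fill_value: float = AIR_HU
) -> VolumeGrid:
    shift = mass_center_shift(volume, body_threshold)
    return apply_shift(volume, shift, fill_value)


def crop_or_pad(volume: VolumeGrid, target_shape, pad_value: float = AIR_HU) -> VolumeGrid:
    """Symmetric center crop and/or pad to ``target_shape``."""
    target_shape = tuple(int(s) for s in target_shape)
    if any(s <= 0 for s in target_shape):
        raise ValueError("target shape must be positive")
    data = volume.intensities
    # crop first
    starts = [max(0, (n - t) // 2) for n, t in zip(data.shape, target_shape)]
    data = data[tuple(slice(s, s + t) for s, t in zip(starts, target_shape))]
    # then pad
    widths = []
    for n, t in zip(data.shape, target_shape):
        d = t - n
        widths.append((d // 2, d - d // 2))
    data = np.pad(data, widths, constant_values=np.float32(pad_value))
    return volume.with_intensities(data)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def fit_normalization(volumes, dataset_id: str = "") -> NormalizationRecord:
    """Global min/max over a list of grids (training split only)."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    lo = min(float(v.intensities.min()) for v in volumes)
    hi = max(float(v.intensities.max()) for v in volumes)
    if hi == lo:
        raise ValueError("degenerate intensity range (max == min)")
    return NormalizationRecord(lo, hi, dataset_id)


def apply_normalization(volume: VolumeGrid, record: NormalizationRecord) -> VolumeGrid:
    scale = 1.0 / (record.global_max - record.global_min)
    data = (volume.intensities.astype(np.float64) - record.global_min) * scale
    return volume.with_intensities(data)


def invert_normalization(volume: VolumeGrid, record: NormalizationRecord) -> VolumeGrid:
    span = record.global_max - record.global_min
    data = volume.intensities.astype(np.float64) * span + record.global_min
    return volume.with_intensities(data)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def sample_affine(policy: AugmentationPolicy, rng: np.random.Generator):
    """Draw one shear-rotate-scale affine; returns (params dict, 3x3 matrix in mm space)."""
    sign = lambda: rng.choice([-1.0, 1.0])
    shear = [sign() * rng.uniform(0, policy.shear_max) for _ in range(3)]
    rot = [sign() * rng.uniform(0, policy.rotation_max) for _ in range(3)]
    scale = [1.0 + sign() * rng.uniform(0, policy.scale_max) for _ in range(3)]

    sh = np.eye(3)
    sh[0, 1], sh[1, 2], sh[2, 0] = shear
    rads = np.deg2rad(rot)
    cz, sz = np.cos(rads[0]), np.sin(rads[0])
    cy, sy = np.cos(rads[1]), np.sin(rads[1])
    cx, sx = np.cos(rads[2]), np.sin(rads[2])
    r0 = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    r1 = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    r2 = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    mat = sh @ (r0 @ r1 @ r2) @ np.diag(scale)
    return {"shear": shear, "rotation_deg": rot, "scale": scale}, mat


def _apply_affine(data, mat_mm, spacing, fill_value):
    # map the mm-space affine into voxel-index space about the grid center
    s = np.diag(spacing)
    m_vox = np.linalg.inv(s) @ mat_mm @ s
    m_inv = np.linalg.inv(m_vox)
    center = (np.array(data.shape) - 1) / 2.0
    offset = center - m_inv @ center
    return ndimage.affine_transform(
        data.astype(np.float32), m_inv, offset=offset, order=1,
        mode="constant", cval=np.float32(fill_value),
    ).astype(np.float32)


def augment_pair(
    volume: VolumeGrid,
    surface: SurfaceMatrix,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
    fill_value: float = AIR_HU,
    return_params: bool = False,
):
    """With probability ``policy.probability``, apply one shared affine to both.

    The identical transform (same drawn parameters) is applied to the volume
    and the surface with trilinear resampling; otherwise both are returned
    unchanged. Deterministic given the rng state.
    """
    if volume.shape != surface.shape:
        raise ValueError("paired grids must share shape")
    apply = rng.uniform() < policy.probability
    params = None
    if apply:
        params, mat = sample_affine(policy, rng)
        vol_out = volume.with_intensities(
            _apply_affine(volume.intensities, mat, volume.spacing, fill_value)
        )
        surf_out = surface.with_intensities(
            _apply_affine(surface.intensities, mat, surface.spacing, fill_value)
        )
    else:
        vol_out, surf_out = volume.copy(), surface.copy()
    if return_params:
        return vol_out, surf_out, params
    return vol_out, surf_out


# ---------------------------------------------------------------------------
# coarse-stage resolution changes
# ---------------------------------------------------------------------------


def downsample_half(volume: VolumeGrid) -> VolumeGrid:
    """Factor-2 trilinear down-sampling (mean of 2x2x2 blocks = trilinear at
    block centers); shape must be even along every axis."""
    if any(n % 2 for n in volume.shape):
        raise ValueError("downsample_half requires even shape")
    d = volume.intensities
    n0, n1, n2 = (n // 2 for n in volume.shape)
    data = d.reshape(n0, 2, n1, 2, n2, 2).mean(axis=(1, 3, 5)).astype(np.float32)
    return dataclasses.replace(
        volume,
        intensities=data,
        spacing=tuple(2 * s for s in volume.spacing),
    )


def upsample_to(volume: VolumeGrid, target_shape) -> VolumeGrid:
    """Trilinear up-sampling to an arbitrary target shape."""
    target_shape = tuple(int(s) for s in target_shape)
    data = _resize_trilinear(volume.intensities, target_shape)
    spacing = tuple(
        s * n / t for s, n, t in zip(volume.spacing, volume.shape, target_shape)
    )
    return dataclasses.replace(volume, intensities=data, spacing=spacing)
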