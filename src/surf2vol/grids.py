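"""Volumetric containers and NIfTI I/O.

A :class:`VolumeGrid` is a 3D scalar intensity field on the Hounsfield-unit
scale (or on [0, 1] after normalization) with voxel spacing and origin
metadata; axis order is (H, W, L) = (axial/superior-inferior, coronal,
sagittal). A :class:`SurfaceMatrix` is the same grid in which only the voxels
on the body's outer shell keep their intensity — the sole input of the
surface-to-volume model.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "SurfaceMatrix", "PatientSeries", "load_grid", "save_grid"]


@dataclasses.dataclass
class VolumeGrid:
    """3D intensity grid with physical metadata.

    Parameters
    ----------
    intensities : (H, W, L) float array, finite.
    spacing : mm per voxel along each axis, strictly positive.
    origin : mm offset of the first voxel, default zero.
    """

    intensities: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.dtype != np.float64:  # keep doubles when provided
            self.intensities = self.intensities.astype(np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("intensities must be a non-empty 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def copy(self) -> "VolumeGrid":
        return dataclasses.replace(self, intensities=self.intensities.copy())

    def with_intensities(self, data: np.ndarray) -> "VolumeGrid":
        return dataclasses.replace(self, intensities=np.asarray(data))


@dataclasses.dataclass
class SurfaceMatrix(VolumeGrid):
    """A grid whose non-background voxels form the body's one-voxel shell."""

    background_value: float = -1000.0

    def shell_mask(self) -> np.ndarray:
        return self.intensities != np.float32(self.background_value)

    def with_intensities(self, data: np.ndarray) -> "SurfaceMatrix":
        return dataclasses.replace(self, intensities=np.asarray(data))


@dataclasses.dataclass
class PatientSeries:
    """Ordered respiratory phases for one patient.

    ``phases`` holds (phase_fraction, volume, surface) triples at fractions
    k / n_phases; all grids share shape and spacing.
    """

    patient_id: str
    phases: list  # of (float, VolumeGrid, SurfaceMatrix)
    rng_seed: int = 0

    def __post_init__(self):
        fracs = [p[0] for p in self.phases]
        if len(set(np.round(fracs, 6))) != len(fracs):
            raise ValueError("phase fractions must be distinct")
        shapes = {p[1].shape for p in self.phases} | {p[2].shape for p in self.phases}
        spacings = {p[1].spacing for p in self.phases} | {p[2].spacing for p in self.phases}
        if len(shapes) > 1 or len(spacings) > 1:
            raise ValueError("all grids in a series must share shape and spacing")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def phase(self, fraction: float):
        for f, vol, surf in self.phases:
            if abs(f - fraction) < 1e-6:
                return vol, surf
        raise KeyError(f"no phase at fraction {fraction}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def save_grid(grid: VolumeGrid, path) -> Path:
    """Write a grid as NIfTI with spacing in the header (diagonal affine)."""
    path = Path(path)
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.intensities.astype(np.float32), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    return path


def load_grid(path, surface: bool = False, background_value: float = -1000.0):
    """Read a NIfTI volume back into a :class:`VolumeGrid`/:class:`SurfaceMatrix`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if surface:
        return SurfaceMatrix(data, spacing, origin, background_value=background_value)
    return VolumeGrid(data, spacing, origin)


_PHASE_RE = re.compile(r"pt(?P<pid>[A-Za-z0-9]+)_phase(?P<k>\d+)(?P<surf>_surf)?\.nii(\.gz)?$")


def phase_filename(patient_id: str, k: int, surface: bool = False) -> str:
    suffix = "_surf" if surface else ""
    return f"pt{patient_id}_phase{k}{suffix}.nii.gz"


def parse_phase_filename(name: str):
    """Return (patient_id, phase_index, is_surface) or None."""
    m = _PHASE_RE.search(str(name))
    if not m:
        return None
    return m.group("pid"), int(m.group("k")), bool(m.group("surf"))
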