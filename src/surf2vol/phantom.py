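"""Synthetic 4D respiratory phantom.

Clinical 4DCT series (10 respiratory phase volumes per patient) are not
distributable, so this module generates per-patient series of smoothly
deforming CT-like body volumes in which the *surface carries information
about the interior*: one cyclic phase parameter drives both the chest-wall
expansion (visible on the body surface) and the superior–inferior translation
of a tumor sphere inside a lung. A surface-to-volume model can therefore
learn the mapping from the shell alone, which is the premise of the method.

Anatomy, on the Hounsfield scale: air exterior (−1000 HU), a bumpy breathing
ellipsoidal body of soft tissue (~40 HU) with a denser skin rind, two
low-density lungs (~−800 HU), a high-density spine rod, a moving tumor
sphere, a few seeded soft-tissue blobs for inter-patient variability, and
additive Gaussian noise.

Axis convention: axis 0 = superior–inferior (axial), axis 1 = coronal
(anterior–posterior), axis 2 = sagittal (left–right).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import PatientSeries, SurfaceMatrix, VolumeGrid

__all__ = [
    "PhantomParams",
    "generate_phantom",
    "generate_patient_series",
    "extract_surface",
]

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclasses.dataclass
class PhantomParams:
    """Geometry and intensity parameters of the respiratory phantom.

    All lengths in mm, all intensities in HU. Defaults define the study
    conditions used throughout the test suite: a 40x64x40 grid at
    (4, 3, 3) mm spacing, 12 mm of superior–inferior tumor motion and a 5 mm
    chest-wall breathing amplitude driven by the same cyclic phase.
    """

    shape: tuple = (40, 64, 40)
    spacing: tuple = (4.0, 3.0, 3.0)
    body_semiaxes: tuple = (70.0, 80.0, 50.0)
    shell_thickness: float = 4.0
    lung_semiaxes: tuple = (45.0, 35.0, 18.0)
    lung_offset: tuple = (0.0, 5.0, 26.0)  # mirrored in the sagittal axis
    n_extra_organs: int = 3
    organ_intensity_range: tuple = (10.0, 70.0)
    tumor_center: tuple = (0.0, 5.0, 26.0)
    tumor_radius: float = 10.0
    motion_amplitude: float = 12.0
    breathing_amplitude: float = 5.0
    bump_amplitude: float = 2.0
    bump_frequency: float = 3.0
    noise_sigma: float = 15.0
    air_hu: float = -1000.0
    soft_tissue_hu: float = 40.0
    skin_hu: float = 55.0
    lung_hu: float = -800.0
    spine_hu: float = 500.0
    spine_offset: float = -45.0  # coronal (posterior) offset of the spine rod
    spine_radius: float = 8.0
    tumor_hu: float = 150.0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for name in ("body_semiaxes", "lung_semiaxes"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if self.tumor_radius <= 0 or self.shell_thickness <= 0:
            raise ValueError("radii/thicknesses must be positive")
        if self.motion_amplitude < 0 or self.breathing_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        half_extent = [sh * sp / 2.0 for sh, sp in zip(self.shape, self.spacing)]
        margin = self.bump_amplitude + 1.0
        semi = list(self.body_semiaxes)
        semi[1] += self.breathing_amplitude / 2.0
        if any(s + margin > h for s, h in zip(semi, half_extent)):
            raise ValueError("body (incl. breathing/bumps) exceeds the grid")
        # tumor must stay inside the body over the whole cycle
        for dz in (self.motion_amplitude / 2.0, -self.motion_amplitude / 2.0):
            c = np.array(self.tumor_center) + np.array([dz, 0.0, 0.0])
            rho = np.sqrt(np.sum((c / np.array(self.body_semiaxes)) ** 2))
            if rho + self.tumor_radius / min(self.body_semiaxes) > 1.0:
                raise ValueError("tumor leaves the body over the motion cycle")


def _grid_mm(params: PhantomParams):
    """Physical coordinates (mm) of voxel centers, origin at the grid center."""
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * sp
        for n, sp in zip(params.shape, params.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _bump_field(params: PhantomParams, seed: int, u):
    """Smooth seeded radial perturbation (mm) as a function of direction."""
    rng = np.random.default_rng([int(seed), 424242])
    n_modes = 6
    dirs = rng.normal(size=(n_modes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    amps = rng.normal(size=n_modes)
    field = np.zeros_like(u[0])
    for d, ph, a in zip(dirs, phases, amps):
        proj = d[0] * u[0] + d[1] * u[1] + d[2] * u[2]
        field += a * np.cos(params.bump_frequency * np.pi * proj + ph)
    rms = np.sqrt(np.mean(field**2))
    if rms > 0:
        field *= params.bump_amplitude / rms
    return field


def _patient_variation(params: PhantomParams, seed: int) -> PhantomParams:
    """Seeded per-patient anatomy jitter (±8% body semi-axes)."""
    rng = np.random.default_rng([int(seed), 7])
    factors = rng.uniform(0.92, 1.08, size=3)
    semi = tuple(float(s * f) for s, f in zip(params.body_semiaxes, factors))
    return dataclasses.replace(params, body_semiaxes=semi)


def generate_phantom(params: PhantomParams, phase: float, seed: int) -> VolumeGrid:
    """Render one respiratory phase of the phantom.

    ``phase`` is the respiratory fraction in [0, 1); the cyclic driver is
    cos(2*pi*phase), so phases 0.0 and 0.5 are the motion extremes and the
    tumor centroid separates by exactly ``motion_amplitude`` between them.
    Deterministic given (params, phase, seed).
    """
    if not (0.0 <= phase < 1.0):
        raise ValueError(f"phase must lie in [0, 1), got {phase}")
    params.validate()

    zz, yy, xx = _grid_mm(params)
    driver = np.cos(2.0 * np.pi * phase)

    a, b, c = params.body_semiaxes
    b_t = b + params.breathing_amplitude / 2.0 * driver  # chest wall expansion
    r = np.sqrt(zz**2 + yy**2 + xx**2) + 1e-9
    u = (zz / r, yy / r, xx / r)
    bump = _bump_field(params, seed, u)
    rbar = (a + b_t + c) / 3.0
    m = np.sqrt((zz / a) ** 2 + (yy / b_t) ** 2 + (xx / c) ** 2)
    body = m <= 1.0 + bump / rbar

    vol = np.full(params.shape, params.air_hu, dtype=np.float64)
    vol[body] = params.soft_tissue_hu

    # denser skin rind just inside the surface
    rind = body & (m >= (1.0 + bump / rbar) * (1.0 - params.shell_thickness / rbar))
    vol[rind] = params.skin_hu

    # seeded extra soft-tissue blobs (patient-specific texture)
    rng_org = np.random.default_rng([int(seed), 13])
    lo, hi = params.organ_intensity_range
    for _ in range(int(params.n_extra_organs)):
        center = rng_org.uniform(-0.45, 0.45, size=3) * np.array([a, b, c])
        radii = rng_org.uniform(8.0, 18.0, size=3)
        hu = rng_org.uniform(lo, hi)
        blob = (
            ((zz - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2
            + ((xx - center[2]) / radii[2]) ** 2
        ) <= 1.0
        vol[blob & body & (m < 0.85)] = hu

    # lungs, mirrored in the sagittal axis
    la, lb, lc = params.lung_semiaxes
    oz, oy, ox = params.lung_offset
    for sx in (+1.0, -1.0):
        lung = (
            ((zz - oz) / la) ** 2
            + ((yy - oy) / lb) ** 2
            + ((xx - sx * ox) / lc) ** 2
        ) <= 1.0
        vol[lung & body & (m < 0.9)] = params.lung_hu

    # spine rod along the superior–inferior axis
    spine = (yy - params.spine_offset) ** 2 + xx**2 <= params.spine_radius**2
    vol[spine & body & (m < 0.95)] = params.spine_hu

    # tumor sphere translating with the respiratory driver
    dz = params.motion_amplitude / 2.0 * driver
    tz, ty, tx = params.tumor_center
    tumor = (zz - (tz + dz)) ** 2 + (yy - ty) ** 2 + (xx - tx) ** 2 <= params.tumor_radius**2
    vol[tumor & body] = params.tumor_hu

    if params.noise_sigma > 0:
        rng_noise = np.random.default_rng([int(seed), int(round(phase * 1e6)), 99])
        vol += rng_noise.normal(0.0, params.noise_sigma, size=vol.shape)

    return VolumeGrid(vol.astype(np.float32), params.spacing)


def generate_patient_series(
    params: PhantomParams, n_phases: int = 10, seed: int = 0
) -> PatientSeries:
    """Generate one patient's phase-resolved (volume, surface) series.

    Patient-level anatomy (surface bumps, organ blobs, semi-axis jitter) is a
    deterministic function of ``seed``; phases sit at fractions k/n_phases.
    """
    if n_phases < 2:
        raise ValueError("a respiratory series needs at least 2 phases")
    pparams = _patient_variation(params, seed)
    phases = []
    for k in range(n_phases):
        frac = k / n_phases
        vol = generate_phantom(pparams, frac, seed)
        surf = extract_surface(vol)
        phases.append((frac, vol, surf))
    return PatientSeries(patient_id=str(seed), phases=phases, rng_seed=int(seed))


def body_mask(volume: VolumeGrid, body_threshold: float = -400.0) -> np.ndarray:
    """Binary body mask: threshold, 6-connected hole filling, largest component."""
    mask = volume.intensities >= body_threshold
    if not mask.any():
        raise ValueError("empty body mask: no voxel reaches the body threshold")
    mask = ndimage.binary_fill_holes(mask, structure=_CROSS)
    labels, n = ndimage.label(mask, structure=_CROSS)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def extract_surface(
    volume: VolumeGrid,
    body_threshold: float = -400.0,
    background_value: float = -1000.0,
) -> SurfaceMatrix:
    """Keep original intensities only on the body's outer shell.

    The shell is the set of body-mask voxels 6-adjacent to at least one
    exterior voxel (voxels beyond the grid count as exterior); everything
    else is set to ``background_value``. Because the mask is hole-filled
    first, re-extracting an extracted surface reproduces the same shell.
    """
    mask = body_mask(volume, body_threshold)
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    shell = mask & ~interior
    out = np.full(volume.shape, background_value, dtype=np.float32)
    out[shell] = volume.intensities[shell]
    return SurfaceMatrix(
        out, volume.spacing, volume.origin, background_value=background_value
    )
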