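"""Image-quality metrics and the grouping / surface-curvature analysis.

Metrics are computed in Hounsfield units inside the patient's body (the
filled mask bounded by the surface; exterior air is excluded):

* MAE — mean absolute CT-number error over body voxels;
* PSNR — ``20 log10(range) - 10 log10(MSE)`` in dB, MSE over body voxels;
* SSIM — mean local structural similarity (Wang et al. constants
  C1=(0.01 range)^2, C2=(0.03 range)^2) with a 7^3 uniform window in 3D,
  averaged over body-centered windows.

Cases are grouped by k-means (k=3 by default) on the z-scored
(MAE, PSNR, SSIM) vectors, labels ordered by ascending group-mean MAE so
group 1 is the best-reconstructed group; t-SNE provides a 2D visualization
of the same standardized metric space. Surface complexity is summarized by
the coefficient of variation (std/mean) of discrete mean-curvature
magnitudes over a marching-cubes mesh of the body surface.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

import trimesh

from .grids import SurfaceMatrix, VolumeGrid
from .phantom import body_mask

__all__ = [
    "CaseMetrics",
    "GroupAssignment",
    "CurvatureSummary",
    "mae_hu",
    "psnr",
    "ssim",
    "evaluate_case",
    "mean_volume_baseline",
    "cluster_cases",
    "tsne_embed",
    "surface_curvature_cov",
    "export_surface_mesh",
]


@dataclasses.dataclass
class CaseMetrics:
    case_id: str
    mae: float  # HU
    psnr: float  # dB
    ssim: float  # unitless, <= 1

    def __post_init__(self):
        if self.mae < 0:
            raise ValueError("MAE must be non-negative")
        if self.ssim > 1.0 + 1e-9:
            raise ValueError("SSIM cannot exceed 1")

    def vector(self) -> np.ndarray:
        return np.array([self.mae, self.psnr, self.ssim], dtype=float)


@dataclasses.dataclass
class GroupAssignment:
    labels: dict  # case_id -> group in 1..k
    centroids: np.ndarray  # (k, 3) in standardized metric space
    k: int
    seed: int


@dataclasses.dataclass
class CurvatureSummary:
    case_id: str
    magnitudes: np.ndarray
    cov: float


# ---------------------------------------------------------------------------
# voxel metrics
# ---------------------------------------------------------------------------


def _as_mask(mask, shape) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return mask


def _data(v) -> np.ndarray:
    return v.intensities if isinstance(v, VolumeGrid) else np.asarray(v)


def mae_hu(pred, truth, mask) -> float:
    """Mean absolute error (HU) over the body mask only."""
    p, t = _data(pred), _data(truth)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    m = _as_mask(mask, p.shape)
    return float(np.mean(np.abs(p[m] - t[m])))


def psnr(pred, truth, data_range: float, mask=None, cap_db: float = 200.0) -> float:
    """Peak signal-to-noise ratio in dB over the mask (full grid if None).

    Identical inputs would give infinite PSNR; the value is capped at
    ``cap_db`` to keep downstream statistics finite.
    """
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    p, t = _data(pred), _data(truth)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    if mask is None:
        mse = float(np.mean((p - t) ** 2))
    else:
        m = _as_mask(mask, p.shape)
        mse = float(np.mean((p[m] - t[m]) ** 2))
    if mse == 0:
        return float(cap_db)
    return min(float(20 * np.log10(data_range) - 10 * np.log10(mse)), cap_db)


def ssim(pred, truth, data_range: float, window: int = 7, mask=None) -> float:
    """Mean local SSIM with a uniform 3D window.

    The local SSIM map is computed at every voxel (uniform filter with
    reflective boundaries) and averaged over mask-centered windows when a
    mask is given, otherwise over the window-valid interior.
    """
    p = _data(pred).astype(np.float64)
    t = _data(truth).astype(np.float64)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    if window > min(p.shape):
        raise ValueError("window larger than grid")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    filt = lambda a: ndimage.uniform_filter(a, size=window, mode="reflect")
    mu_p = filt(p)
    mu_t = filt(t)
    var_p = filt(p * p) - mu_p**2
    var_t = filt(t * t) - mu_t**2
    cov = filt(p * t) - mu_p * mu_t
    ssim_map = ((2 * mu_p * mu_t + c1) * (2 * cov + c2)) / (
        (mu_p**2 + mu_t**2 + c1) * (var_p + var_t + c2)
    )
    if mask is not None:
        m = _as_mask(mask, p.shape)
        return float(ssim_map[m].mean())
    half = window // 2
    interior = tuple(slice(half, s - half) for s in p.shape)
    return float(ssim_map[interior].mean())


def evaluate_case(
    case_id: str,
    pred: VolumeGrid,
    truth: VolumeGrid,
    data_range: float,
    body_threshold: float = -400.0,
) -> CaseMetrics:
    """MAE/PSNR/SSIM of a predicted HU volume against ground truth, inside
    the truth volume's body mask."""
    mask = body_mask(truth, body_threshold)
    return CaseMetrics(
        case_id=case_id,
        mae=mae_hu(pred, truth, mask),
        psnr=psnr(pred, truth, data_range, mask),
        ssim=ssim(pred, truth, data_range, mask=mask),
    )


def mean_volume_baseline(volumes) -> VolumeGrid:
    """Voxel-wise mean of the training volumes — the anatomically static
    baseline a useful surface-to-volume model must beat."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    stack = np.stack([v.intensities for v in volumes])
    return dataclasses.replace(volumes[0], intensities=stack.mean(axis=0))


# ---------------------------------------------------------------------------
# grouping analysis
# ---------------------------------------------------------------------------


def _standardize(vectors: np.ndarray):
    mu = vectors.mean(axis=0)
    sd = vectors.std(axis=0)
    sd[sd == 0] = 1.0
    return (vectors - mu) / sd


def cluster_cases(metrics, k: int = 3, seed: int = 0) -> GroupAssignment:
    """k-means over z-scored (MAE, PSNR, SSIM); groups renumbered 1..k by
    ascending mean MAE (group 1 = best)."""
    metrics = list(metrics)
    if len(metrics) < k:
        raise ValueError(f"need at least k={k} cases, got {len(metrics)}")
    vectors = np.stack([m.vector() for m in metrics])
    z = _standardize(vectors)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    raw = km.fit_predict(z)
    # order group labels by ascending mean MAE
    order = np.argsort(
        [vectors[raw == g, 0].mean() if (raw == g).any() else np.inf for g in range(k)]
    )
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = {m.case_id: relabel[int(g)] for m, g in zip(metrics, raw)}
    centroids = km.cluster_centers_[order]
    return GroupAssignment(labels=labels, centroids=centroids, k=k, seed=int(seed))


def tsne_embed(metrics, seed: int = 0) -> np.ndarray:
    """2D t-SNE embedding of the standardized metric vectors (one row per
    case); visualization only — finite and reproducible at fixed seed."""
    metrics = list(metrics)
    if len(metrics) < 5:
        raise ValueError("t-SNE needs at least 5 cases")
    z = _standardize(np.stack([m.vector() for m in metrics]))
    perplexity = min(30.0, max(2.0, (len(metrics) - 1) / 3.0))
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=int(seed),
        max_iter=500,
    )
    return ts.fit_transform(z)


# ---------------------------------------------------------------------------
# surface curvature
# ---------------------------------------------------------------------------


def _cotangent_mean_curvature(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex mean-curvature magnitude |H| via the cotangent Laplacian.

    |H_i| = ||sum_j w_ij (x_j - x_i)|| / (2 A_i) with the usual half-cotangent
    edge weights and barycentric vertex areas A_i.
    """
    v = vertices.astype(np.float64)
    lap = np.zeros_like(v)
    area = np.zeros(len(v))
    for k in range(3):
        a = faces[:, k]
        b = faces[:, (k + 1) % 3]
        c = faces[:, (k + 2) % 3]
        u = v[b] - v[a]
        w = v[c] - v[a]
        cross = np.cross(u, w)
        cross_norm = np.linalg.norm(cross, axis=1)
        cross_norm = np.maximum(cross_norm, 1e-12)
        cot = (u * w).sum(axis=1) / cross_norm  # cotangent at corner a
        weight = 0.5 * cot[:, None]
        np.add.at(lap, b, weight * (v[c] - v[b]))
        np.add.at(lap, c, weight * (v[b] - v[c]))
        if k == 0:  # barycentric area, once per face
            np.add.at(area, faces[:, 0], cross_norm / 6.0)
            np.add.at(area, faces[:, 1], cross_norm / 6.0)
            np.add.at(area, faces[:, 2], cross_norm / 6.0)
    area = np.maximum(area, 1e-12)
    return np.linalg.norm(lap, axis=1) / (2.0 * area)


def _smooth_vertex_field(field, faces, n_verts, iterations=2):
    """Uniform 1-ring averaging of a per-vertex scalar field."""
    nbr_sum = None
    for _ in range(iterations):
        acc = np.zeros(n_verts)
        cnt = np.zeros(n_verts)
        for k in range(3):
            a = faces[:, k]
            b = faces[:, (k + 1) % 3]
            np.add.at(acc, a, field[b])
            np.add.at(acc, b, field[a])
            np.add.at(cnt, a, 1.0)
            np.add.at(cnt, b, 1.0)
        field = acc / np.maximum(cnt, 1.0)
    return field


def surface_curvature_cov(
    surface: SurfaceMatrix,
    case_id: str = "",
    smoothing_iterations: int = 15,
    curvature_smoothing: int = 5,
) -> CurvatureSummary:
    """Coefficient of variation of mean-curvature magnitudes on the body
    surface.

    The shell is filled and triangulated by marching cubes; the mesh is
    Taubin-smoothed to suppress voxelization terracing; the discrete mean
    curvature (cotangent Laplacian norm / 2, barycentric areas) is evaluated
    per vertex, lightly averaged over 1-ring neighborhoods, and its
    magnitude distribution summarized by COV = std/mean. Signs are
    discarded — only the spread of curvature magnitude matters — and COV is
    scale-free: uniformly rescaling the body leaves it unchanged.
    """
    mask = ndimage.binary_fill_holes(
        surface.shell_mask(), structure=ndimage.generate_binary_structure(3, 1)
    )
    if mask.sum() < 8:
        raise ValueError("degenerate surface: too few voxels")
    # a Gaussian-smoothed indicator avoids the 45-degree terracing a binary
    # marching-cubes surface would imprint on the curvature field
    field = ndimage.gaussian_filter(mask.astype(np.float32), sigma=1.5)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=surface.spacing
    )
    if len(verts) < 4:
        raise ValueError("degenerate mesh")
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if smoothing_iterations > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=smoothing_iterations)
    vv = np.asarray(mesh.vertices)
    ff = np.asarray(mesh.faces)
    magnitudes = _cotangent_mean_curvature(vv, ff)
    if curvature_smoothing > 0:
        magnitudes = _smooth_vertex_field(magnitudes, ff, len(vv), curvature_smoothing)
    mean_mag = float(magnitudes.mean())
    if mean_mag <= 0:
        raise ValueError("curvature magnitudes have zero mean")
    cov = float(magnitudes.std() / mean_mag)
    return CurvatureSummary(case_id=case_id, magnitudes=magnitudes, cov=cov)


def export_surface_mesh(surface: SurfaceMatrix, path) -> "trimesh.Trimesh":
    """Triangulate the body surface and write it as a PLY mesh.

    Uses the same marching-cubes/smoothing pipeline as the curvature
    analysis so the exported geometry matches what the COV is computed on.
    """
    mask = ndimage.binary_fill_holes(
        surface.shell_mask(), structure=ndimage.generate_binary_structure(3, 1)
    )
    field = ndimage.gaussian_filter(mask.astype(np.float32), sigma=1.5)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=surface.spacing
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.export(str(path))
    return mesh
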