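"""Metric oracles, grouping analysis, surface curvature."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from surf2vol import (
    cluster_cases,
    mae_hu,
    mean_volume_baseline,
    psnr,
    ssim,
    surface_curvature_cov,
    tsne_embed,
)
from surf2vol.evaluation import CaseMetrics
from surf2vol.grids import VolumeGrid

from conftest import digitized_surface


def brute_force_ssim(p, t, data_range, window=7):
    """Sliding-window SSIM by explicit loops (reflect-padded), full map."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    half = window // 2
    pp = np.pad(p.astype(np.float64), half, mode="reflect")
    tt = np.pad(t.astype(np.float64), half, mode="reflect")
    out = np.zeros(p.shape)
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            for k in range(p.shape[2]):
                wp = pp[i : i + window, j : j + window, k : k + window]
                wt = tt[i : i + window, j : j + window, k : k + window]
                mp, mt = wp.mean(), wt.mean()
                vp = (wp * wp).mean() - mp * mp
                vt = (wt * wt).mean() - mt * mt
                cov = (wp * wt).mean() - mp * mt
                out[i, j, k] = ((2 * mp * mt + c1) * (2 * cov + c2)) / (
                    (mp * mp + mt * mt + c1) * (vp + vt + c2)
                )
    return out


class TestMetricOracles:
    def test_mae_masked(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 100, size=(6, 6, 6))
        p = t.copy() + 10.0
        mask = np.zeros(t.shape, bool)
        mask[1:5, 1:5, 1:5] = True
        p[~mask] = 9999.0  # garbage outside the mask must not matter
        assert mae_hu(p, t, mask) == pytest.approx(10.0)

    def test_mae_brute_force(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(4, 4, 4))
        p = rng.normal(size=(4, 4, 4))
        mask = rng.uniform(size=(4, 4, 4)) > 0.4
        ref = np.mean([abs(p[i] - t[i]) for i in np.ndindex(4, 4, 4) if mask[i]])
        assert mae_hu(p, t, mask) == pytest.approx(ref, rel=1e-9)

    def test_psnr_closed_form(self):
        p = np.full((8, 8, 8), 0.1)
        t = np.zeros((8, 8, 8))
        assert psnr(p, t, 1.0) == pytest.approx(20.0, abs=1e-9)
        # doubling a uniform error costs ~6.02 dB
        assert psnr(p * 2, t, 1.0) == pytest.approx(20.0 - 20 * np.log10(2), abs=1e-9)

    def test_psnr_identical_capped(self):
        t = np.ones((4, 4, 4))
        assert psnr(t, t, 1.0, cap_db=120.0) == 120.0

    def test_psnr_bad_range(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), 0.0)

    def test_ssim_identical_is_one(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=(10, 10, 10))
        assert ssim(t, t, 2.0) == pytest.approx(1.0)

    def test_ssim_inverted_below_one(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 1, size=(10, 10, 10))
        p = 1.0 - t
        assert ssim(p, t, 1.0) < 1.0

    def test_ssim_window_too_large(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), 1.0, window=7)

    def test_ssim_matches_brute_force_map(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0, 1, size=(8, 8, 8))
        p = t + rng.normal(0, 0.1, size=t.shape)
        mask = np.zeros(t.shape, bool)
        mask[3:5, 3:5, 3:5] = True  # interior windows only
        mine = ssim(p, t, 1.0, mask=mask)
        ref = brute_force_ssim(p, t, 1.0)[mask].mean()
        assert mine == pytest.approx(ref, rel=1e-6)

    def test_directional_coherence_under_noise(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(-500, 500, size=(12, 12, 12))
        mask = np.ones(t.shape, bool)
        maes, psnrs, ssims = [], [], []
        for sigma in [5, 20, 50, 120, 300]:
            p = t + rng.normal(0, sigma, size=t.shape)
            maes.append(mae_hu(p, t, mask))
            psnrs.append(psnr(p, t, 1000.0, mask))
            ssims.append(ssim(p, t, 1000.0, mask=mask))
        assert np.all(np.diff(maes) > 0)
        assert np.all(np.diff(psnrs) < 0)
        assert np.all(np.diff(ssims) < 0)


def make_metric_clouds(seed, n_per=12, sep=10.0):
    """Three well-separated Gaussian clouds in (MAE, PSNR, SSIM) space."""
    rng = np.random.default_rng(seed)
    centers = [(30.0, 39.0, 0.96), (45.0, 35.0, 0.93), (60.0, 31.0, 0.90)]
    sds = np.array([1.0, 0.3, 0.003])
    metrics, labels = [], []
    for g, c in enumerate(centers):
        for i in range(n_per):
            v = np.array(c) + rng.normal(size=3) * sds / (sep / 10.0) * (10.0 / sep)
            metrics.append(
                CaseMetrics(f"g{g}c{i}", max(v[0], 0), v[1], min(v[2], 1.0))
            )
            labels.append(g)
    return metrics, labels


class TestClustering:
    def test_k1_single_group(self):
        metrics, _ = make_metric_clouds(0, n_per=4)
        groups = cluster_cases(metrics, k=1, seed=0)
        assert set(groups.labels.values()) == {1}
        vectors = np.stack([m.vector() for m in metrics])
        z = (vectors - vectors.mean(0)) / vectors.std(0)
        np.testing.assert_allclose(groups.centroids[0], z.mean(0), atol=1e-6)

    def test_recovers_separated_clouds(self):
        metrics, labels = make_metric_clouds(1)
        groups = cluster_cases(metrics, k=3, seed=0)
        pred = [groups.labels[m.case_id] for m in metrics]
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_group_one_has_lowest_mae(self):
        metrics, _ = make_metric_clouds(2)
        groups = cluster_cases(metrics, k=3, seed=0)
        by_group = {}
        for m in metrics:
            by_group.setdefault(groups.labels[m.case_id], []).append(m.mae)
        means = [np.mean(by_group[g]) for g in sorted(by_group)]
        assert means == sorted(means)

    def test_permutation_invariance(self):
        metrics, _ = make_metric_clouds(3)
        a = cluster_cases(metrics, k=3, seed=7).labels
        b = cluster_cases(metrics[::-1], k=3, seed=7).labels
        assert a == b

    def test_too_few_cases(self):
        metrics, _ = make_metric_clouds(0, n_per=1)
        with pytest.raises(ValueError):
            cluster_cases(metrics[:2], k=3, seed=0)


class TestTSNE:
    def test_finite_and_reproducible(self):
        metrics, _ = make_metric_clouds(4, n_per=5)
        a = tsne_embed(metrics, seed=1)
        b = tsne_embed(metrics, seed=1)
        assert a.shape == (len(metrics), 2)
        assert np.all(np.isfinite(a))
        np.testing.assert_array_equal(a, b)

    def test_duplicate_case_coincides(self):
        metrics, _ = make_metric_clouds(5, n_per=5)
        dup = CaseMetrics("dup", metrics[0].mae, metrics[0].psnr, metrics[0].ssim)
        emb = tsne_embed(metrics + [dup], seed=2)
        d_dup = np.linalg.norm(emb[0] - emb[-1])
        diameter = np.max(
            np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        )
        assert d_dup < 0.1 * diameter

    def test_too_few_cases(self):
        metrics, _ = make_metric_clouds(0, n_per=1)
        with pytest.raises(ValueError):
            tsne_embed(metrics, seed=0)


class TestCurvature:
    def test_sphere_near_constant_curvature(self, sphere_surface):
        summary = surface_curvature_cov(sphere_surface)
        assert summary.cov < 0.15
        # digitized radius-20 sphere: |H| should approximate 1/20
        assert summary.magnitudes.mean() == pytest.approx(0.05, rel=0.25)

    def test_ellipsoid_exceeds_sphere(self, sphere_surface, ellipsoid_surface):
        assert (
            surface_curvature_cov(ellipsoid_surface).cov
            > surface_curvature_cov(sphere_surface).cov
        )

    def test_uniform_scaling_invariance(self, sphere_surface):
        c1 = surface_curvature_cov(sphere_surface).cov
        scaled = digitized_surface(
            lambda z, y, x: z**2 + y**2 + x**2 <= 40.0**2, spacing=(2.0, 2.0, 2.0)
        )
        c2 = surface_curvature_cov(scaled).cov
        assert c2 == pytest.approx(c1, abs=0.02)

    def test_degenerate_surface(self):
        tiny = VolumeGrid(np.full((6, 6, 6), -1000.0, np.float32), (1, 1, 1))
        tiny.intensities[3, 3, 3] = 50.0
        from surf2vol import extract_surface

        surf = extract_surface(tiny)
        with pytest.raises(ValueError):
            surface_curvature_cov(surf)


def test_mean_volume_baseline():
    a = VolumeGrid(np.zeros((4, 4, 4), np.float32), (1, 1, 1))
    b = VolumeGrid(np.full((4, 4, 4), 10.0, np.float32), (1, 1, 1))
    base = mean_volume_baseline([a, b])
    np.testing.assert_allclose(base.intensities, 5.0)


def test_export_surface_mesh_ply(sphere_surface, tmp_path):
    from surf2vol.evaluation import export_surface_mesh

    path = tmp_path / "sphere.ply"
    mesh = export_surface_mesh(sphere_surface, path)
    assert path.exists() and path.stat().st_size > 0
    assert len(mesh.vertices) > 100 and len(mesh.faces) > 100
    assert path.read_bytes().startswith(b"ply")
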