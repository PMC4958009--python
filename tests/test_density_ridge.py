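"""KDE, mean-shift modes, ridge tracing and spur pruning."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from spineridge.density_ridge import (
    KDE,
    BackboneConfig,
    BackboneGraph,
    RidgeCurve,
    extract_backbone,
    find_modes,
    kde_evaluate,
    project_to_ridge,
    prune_spurs,
    segment_curves,
    trace_ridge,
)
from spineridge.errors import ValidationError
from spineridge.io_preprocess import BinaryMask


class TestKDE:
    def test_single_sample_closed_form(self):
        h = 2.0
        kde = KDE([[0.0, 0.0]], h)
        assert kde_evaluate(kde, [0.0, 0.0]) == pytest.approx(
            1.0 / (2 * np.pi * h * h), rel=1e-12
        )

    def test_symmetric_pair_midpoint(self):
        kde = KDE([[0.0, -3.0], [0.0, 3.0]], 2.0)
        one = KDE([[0.0, -3.0]], 2.0)
        assert kde.density([0.0, 0.0]) == pytest.approx(
            one.density([0.0, 0.0]), rel=1e-12
        )

    def test_far_field_decay(self):
        kde = KDE([[0.0, 0.0], [0.0, 1.0]], 1.0)
        near = kde.density([0.0, 0.0])
        far = kde.density([0.0, 12.0])  # > 10 bandwidths away
        assert far < 1e-12 * near

    def test_integrates_to_one(self):
        kde = KDE([[5.0, 5.0], [8.0, 4.0], [2.0, 7.0]], 1.5)
        gs = np.linspace(-5, 18, 180)
        xx, yy = np.meshgrid(gs, gs, indexing="ij")
        grid = np.stack([xx.ravel(), yy.ravel()], axis=1)
        dens = kde.density_batch(grid)
        total = dens.sum() * (gs[1] - gs[0]) ** 2
        assert total == pytest.approx(1.0, rel=0.01)

    def test_singular_bandwidth_rejected(self):
        with pytest.raises(ValidationError):
            KDE([[0.0, 0.0]], np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_gradient_matches_finite_difference(self, rng):
        kde = KDE(rng.random((20, 2)) * 10, 1.5)
        x = np.array([4.7, 5.3])
        eps = 1e-6
        fd = np.array([
            (kde.density(x + [eps, 0]) - kde.density(x - [eps, 0])) / (2 * eps),
            (kde.density(x + [0, eps]) - kde.density(x - [0, eps])) / (2 * eps),
        ])
        np.testing.assert_allclose(kde.gradient(x), fd, atol=1e-8)


class TestFindModes:
    def test_single_sample_is_mode(self):
        kde = KDE([[3.0, 4.0]], 1.0)
        modes = find_modes(kde, [[3.5, 4.5]], tol=1e-6)
        np.testing.assert_allclose(modes[0], [3.0, 4.0], atol=1e-4)

    def test_close_pair_single_midpoint_mode(self):
        kde = KDE([[0.0, -0.2], [0.0, 0.2]], 2.0)
        modes = find_modes(kde, [[0.1, -0.2], [0.1, 0.2]], tol=1e-6)
        assert len(modes) == 1
        np.testing.assert_allclose(modes[0], [0.0, 0.0], atol=1e-3)

    def test_three_clusters_recovered(self, rng):
        centers = np.array([[0.0, 0.0], [0.0, 30.0], [30.0, 15.0]])
        pts = np.concatenate([
            c + rng.normal(0, 1.0, size=(60, 2)) for c in centers
        ])
        kde = KDE(pts, 2.0)
        modes = find_modes(kde, pts[::10], tol=1e-5)
        assert len(modes) == 3
        # each mode near the grid argmax of the KDE around its cluster
        for c in centers:
            d = min(np.linalg.norm(m - c) for m in modes)
            assert d < 1.0

    def test_ascent_monotone(self, rng):
        pts = rng.normal(0, 3, size=(50, 2))
        kde = KDE(pts, 1.5)
        x = np.array([4.0, 4.0])
        prev = kde.density(x)
        for _ in range(40):
            x = kde.mean_shift(x)
            cur = kde.density(x)
            assert cur >= prev - 1e-12
            prev = cur


class TestRidgeProjection:
    def test_mode_is_fixed_point(self, line_kde):
        m = find_modes(line_kde, [[50.0, 50.0]], tol=1e-6)[0]
        p = project_to_ridge(line_kde, m, tol=1e-6)
        assert np.linalg.norm(p - m) < 1e-4

    def test_offset_point_lands_on_line(self, line_kde):
        p = project_to_ridge(line_kde, np.array([53.0, 40.0]), tol=1e-6)
        assert abs(p[0] - 50.0) < 0.5

    def test_symmetry_axis_preserved(self):
        # cross of two perpendicular lines; a point on the vertical
        # symmetry axis stays on it
        ys = np.linspace(-20, 20, 81)
        pts = np.concatenate([
            np.stack([np.zeros_like(ys), ys], axis=1),
            np.stack([ys, np.zeros_like(ys)], axis=1),
        ])
        kde = KDE(pts, 2.0)
        p = project_to_ridge(kde, np.array([5.0, 0.0]), tol=1e-7)
        assert abs(p[1]) < 1e-6


class TestTraceRidge:
    def test_straight_line_traced(self, line_kde):
        mode = find_modes(line_kde, [[50.0, 50.0]], tol=1e-6)[0]
        curve = trace_ridge(line_kde, mode, step=1.5, theta=1e-6,
                            domain=(40, 60, 0, 100))
        interior = curve.points[
            (curve.points[:, 1] > 5) & (curve.points[:, 1] < 95)
        ]
        assert interior.shape[0] > 40
        dev = np.abs(interior[:, 0] - 50.0)
        assert (dev <= 0.5).mean() >= 0.95
        assert curve.points[:, 1].max() - curve.points[:, 1].min() > 80

    def test_circle_traced_at_radius(self):
        r = 30.0
        ang = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        kde = KDE(pts, 3.0)
        seed = project_to_ridge(kde, np.array([r, 0.0]), tol=1e-7)
        curve = trace_ridge(kde, seed, step=2.0, theta=1e-9, max_len=300)
        radii = np.linalg.norm(curve.points, axis=1)
        assert np.abs(radii - r).max() < 0.5

    def test_isotropic_blob_degenerate(self):
        # perfectly isotropic density: samples on a tiny ring << bandwidth;
        # the density drops in every direction, so tracing terminates at
        # once against any meaningful threshold
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = 0.5 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        kde = KDE(pts, 2.0)
        mode = find_modes(kde, [[0.0, 0.0]], tol=1e-6)[0]
        theta = 0.9 * kde.density(mode)
        curve = trace_ridge(kde, mode, step=1.5, theta=theta, max_len=50)
        assert len(curve) <= 3

    def test_below_theta_seed_empty(self, line_kde):
        curve = trace_ridge(line_kde, np.array([50.0, 50.0]), step=1.0,
                            theta=1e9)
        assert len(curve) == 0

    def test_every_point_above_theta(self, line_kde):
        mode = find_modes(line_kde, [[50.0, 50.0]], tol=1e-6)[0]
        theta = 0.2 * line_kde.density(mode)
        curve = trace_ridge(line_kde, mode, step=1.5, theta=theta)
        assert (curve.density > theta).all()


class TestEquivariance:
    def test_translation(self, rng):
        pts = rng.random((60, 2)) * 20
        t = np.array([7.25, -3.5])
        k1 = KDE(pts, 2.0)
        k2 = KDE(pts + t, 2.0)
        m1 = find_modes(k1, pts[::6], tol=1e-6)
        m2 = find_modes(k2, pts[::6] + t, tol=1e-6)
        assert len(m1) == len(m2)
        for a in m1:
            assert min(np.linalg.norm(a + t - b) for b in m2) < 1e-6


class TestSegmentCurves:
    def test_all_above_unchanged(self):
        c = RidgeCurve(np.zeros((6, 2)), np.full(6, 5.0))
        out = segment_curves([c], theta=1.0, min_len=2)
        assert len(out) == 1 and len(out[0]) == 6

    def test_theta_above_max_empty(self):
        c = RidgeCurve(np.zeros((6, 2)), np.full(6, 5.0))
        assert segment_curves([c], theta=10.0, min_len=1) == []

    def test_split_at_low_density(self):
        c = RidgeCurve(np.arange(10).reshape(5, 2), np.array([5, 5, 1, 5, 5.0]))
        out = segment_curves([c], theta=2.0, min_len=1)
        assert [len(s) for s in out] == [2, 2]


def _straight(n, r0, c0, dr, dc):
    pts = np.stack([r0 + dr * np.arange(n), c0 + dc * np.arange(n)], axis=1).astype(float)
    return RidgeCurve(pts, np.ones(n))


class TestPruneSpurs:
    def test_short_perpendicular_branch_removed(self):
        main = _straight(40, 50, 0, 0, 1)
        spur = _straight(8, 51, 20, 1, 0)  # 8 px perpendicular, endpoint near main
        g = prune_spurs(BackboneGraph([main, spur]), junction_radius=3.0,
                        spur_max_len=15.0)
        assert len(g.curves) == 1
        assert g.curves[0].arc_length() == pytest.approx(39.0, abs=1e-9)

    def test_long_branch_kept_as_side_dendrite(self):
        main = _straight(40, 50, 0, 0, 1)
        branch = _straight(30, 51, 20, 1, 0)
        g = prune_spurs(BackboneGraph([main, branch]), junction_radius=3.0,
                        spur_max_len=15.0)
        assert len(g.curves) == 2

    def test_x_crossing_both_survive(self):
        c1 = _straight(41, 30, 30, 1, 1)    # diagonal through (50,50)
        c2 = _straight(41, 70, 30, -1, 1)   # anti-diagonal through (50,50)
        g = prune_spurs(BackboneGraph([c1, c2]), junction_radius=3.0,
                        spur_max_len=15.0)
        total = sum(c.arc_length() for c in g.curves)
        assert total == pytest.approx(2 * 40 * np.sqrt(2), rel=0.05)

    def test_no_junction_identity(self):
        c1 = _straight(20, 10, 0, 0, 1)
        c2 = _straight(20, 80, 0, 0, 1)
        g = prune_spurs(BackboneGraph([c1, c2]), junction_radius=3.0,
                        spur_max_len=15.0)
        assert len(g.curves) == 2


class TestExtractBackbone:
    def _tube_mask(self, shape, row, halfwidth, c0, c1):
        m = np.zeros(shape, dtype=bool)
        m[row - halfwidth: row + halfwidth + 1, c0:c1] = True
        return BinaryMask(m)

    def test_straight_tube_single_curve(self):
        mask = self._tube_mask((100, 220), 50, 3, 10, 210)
        g = extract_backbone(mask, BackboneConfig())
        assert len(g.curves) == 1
        dev = np.abs(g.all_points()[:, 0] - 50.0)
        assert dev.mean() <= 1.0

    def test_two_parallel_tubes(self):
        m = np.zeros((120, 220), dtype=bool)
        m[37:44, 10:210] = True
        m[77:84, 10:210] = True
        g = extract_backbone(BinaryMask(m), BackboneConfig())
        assert len(g.curves) == 2

    def test_y_shape_covered(self):
        m = np.zeros((160, 160), dtype=bool)
        m[77:84, 10:150] = True                     # main bar
        for i in range(60):                          # diagonal branch
            r, c = 77 - i, 80 + i
            m[max(r - 3, 0): r + 4, c - 3: c + 4] |= True
        g = extract_backbone(BinaryMask(m), BackboneConfig())
        assert len(g.curves) >= 2
        from skimage.morphology import skeletonize

        sk = np.argwhere(skeletonize(m))
        d, _ = cKDTree(g.all_points()).query(sk.astype(float))
        assert (d <= 3.0).mean() >= 0.90

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            extract_backbone(BinaryMask(np.zeros((10, 10), bool)), BackboneConfig())
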