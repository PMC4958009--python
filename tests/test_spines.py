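"""Spine candidate detection, geodesic measurement and report totals."""

import numpy as np
import pytest

from spineridge.boundary import DendriteBoundary
from spineridge.errors import ValidationError
from spineridge.io_preprocess import BinaryMask
from spineridge.spines import (
    SpineRegion,
    SpineReport,
    detect_spines,
    filter_pseudo,
    measure_dendrite,
    measure_spine,
    normalize_measurements,
)
from spineridge.density_ridge import BackboneGraph, RidgeCurve

PX = 0.24


def _tube_boundary(row=20.0, c0=5, c1=75, half=3.0):
    pts = np.stack([np.full(c1 - c0, row), np.arange(c0, c1, dtype=float)], axis=1)
    return DendriteBoundary(
        backbone_points=pts,
        left=pts + np.array([half, 0.0]),
        right=pts - np.array([half, 0.0]),
        widths_um=np.full(pts.shape[0], 2 * half * PX),
        alpha=0.5,
    )


class TestDetectSpines:
    def test_no_foreground_outside(self):
        dend = np.zeros((40, 80), dtype=bool)
        dend[17:24, :] = True
        assert detect_spines(BinaryMask(dend), BinaryMask(dend),
                             _tube_boundary()) == []

    def test_attached_component_found(self):
        dend = np.zeros((40, 80), dtype=bool)
        dend[17:24, :] = True
        mask = dend.copy()
        mask[24:32, 30:33] = True  # protrusion below the tube
        regions = detect_spines(BinaryMask(mask), BinaryMask(dend),
                                _tube_boundary(), min_area=4, max_gap=2.0)
        assert len(regions) == 1
        assert np.linalg.norm(regions[0].attachment - [23.0, 31.0]) <= 2.5

    def test_far_component_excluded(self):
        dend = np.zeros((40, 80), dtype=bool)
        dend[17:24, :] = True
        mask = dend.copy()
        mask[32:36, 30:34] = True  # 8 px away from the boundary
        assert detect_spines(BinaryMask(mask), BinaryMask(dend),
                             _tube_boundary(), max_gap=2.0) == []

    def test_min_area_monotone(self):
        dend = np.zeros((40, 80), dtype=bool)
        dend[17:24, :] = True
        mask = dend.copy()
        mask[24:32, 30:33] = True
        mask[24:26, 50:53] = True
        counts = [len(detect_spines(BinaryMask(mask), BinaryMask(dend),
                                    _tube_boundary(), min_area=a))
                  for a in (1, 5, 10, 100)]
        assert counts == sorted(counts, reverse=True)


class TestMeasureSpine:
    def test_straight_protrusion(self):
        # 10-pixel vertical strip attached at its top pixel
        pix = np.stack([np.arange(10, 20), np.full(10, 7)], axis=1)
        region = SpineRegion(pixels=pix, attachment=np.array([9.0, 7.0]))
        length, area = measure_spine(region, PX)
        assert length == pytest.approx(10 * PX)
        assert area == pytest.approx(10 * PX * PX)

    def test_single_pixel_floor(self):
        region = SpineRegion(pixels=np.array([[5, 5]]),
                             attachment=np.array([4.0, 5.0]))
        length, area = measure_spine(region, PX)
        assert length == pytest.approx(1 * PX)
        assert area == pytest.approx(PX * PX)

    def test_l_shape_geodesic_vs_oracle(self):
        # 5 px down then 4 px right; geodesic = 9-pixel path, not the
        # euclidean tip distance
        pix = [(i, 0) for i in range(5)] + [(4, j) for j in range(1, 5)]
        pix = np.array(pix)
        region = SpineRegion(pixels=pix, attachment=np.array([-1.0, 0.0]))
        length, _ = measure_spine(region, 1.0)
        # independent oracle: dijkstra on the explicit pixel graph
        from scipy.sparse import lil_matrix
        from scipy.sparse.csgraph import dijkstra

        n = pix.shape[0]
        idx = {tuple(p): i for i, p in enumerate(map(tuple, pix))}
        W = lil_matrix((n, n))
        for (r, c), i in idx.items():
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    j = idx.get((r + dr, c + dc))
                    if j is not None and j != i:
                        W[i, j] = np.hypot(dr, dc)
        D = dijkstra(W.tocsr(), indices=0)
        assert length == pytest.approx(D.max() + 1.0)
        # one diagonal shortcut at the corner: 6 unit steps + sqrt(2), +1
        assert length == pytest.approx(7.0 + np.sqrt(2))
        assert length > np.hypot(4, 4) + 1.0  # longer than the tip distance

    def test_detached_attachment_rejected(self):
        region = SpineRegion(pixels=np.array([[5, 5]]),
                             attachment=np.array([20.0, 20.0]))
        with pytest.raises(ValidationError):
            measure_spine(region, PX)


class TestMeasureDendrite:
    def test_straight_100px(self):
        pts = np.stack([np.full(101, 5.0), np.arange(101, dtype=float)], axis=1)
        g = BackboneGraph([RidgeCurve(pts, np.ones(101))])
        assert measure_dendrite(g, 0.24) == pytest.approx(24.0)

    def test_additivity(self):
        p1 = np.stack([np.full(101, 5.0), np.arange(101, dtype=float)], axis=1)
        p2 = np.stack([np.full(51, 9.0), np.arange(51, dtype=float)], axis=1)
        g = BackboneGraph([RidgeCurve(p1, np.ones(101)),
                           RidgeCurve(p2, np.ones(51))])
        assert measure_dendrite(g, 0.24) == pytest.approx(36.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            measure_dendrite(BackboneGraph([]), 0.24)


class TestNormalize:
    def test_direct_substitution(self):
        assert normalize_measurements([0, 5, 10]) == pytest.approx([0, 0.5, 1.0])

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            normalize_measurements([3, 3, 3])

    def test_scale_invariant(self, rng):
        vals = rng.random(10).tolist()
        a = normalize_measurements(vals)
        b = normalize_measurements([7.3 * v for v in vals])
        np.testing.assert_allclose(a, b)


class TestFilterPseudo:
    def test_empty_candidates(self):
        from spineridge.tsvm import TSVMModel

        m = TSVMModel(mode="linear", z1=np.array([1.0, 0.0]),
                      z2=np.array([1.0, -5.0]), c1=1, c2=1)
        assert filter_pseudo([], m) == ([], [])

    def test_untrained_rejected(self):
        region = SpineRegion(pixels=np.array([[0, 0]]),
                             attachment=np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            filter_pseudo([region], None)


class TestReport:
    def test_totals_are_sums(self):
        regions = []
        for k in range(3):
            pix = np.stack([np.arange(10 + k, 20), np.full(10 - k, 7 + 10 * k)],
                           axis=1)
            r = SpineRegion(pixels=pix, attachment=pix[0] - [1, 0])
            measure_spine(r, PX)
            regions.append(r)
        rep = SpineReport.from_spines(50.0, regions)
        assert rep.spine_count == 3
        assert rep.total_spine_length_um == sum(r.length_um for r in regions)
        assert rep.total_spine_area_um2 == sum(r.area_um2 for r in regions)
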