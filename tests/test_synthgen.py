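"""Generative point model, image rendering and the labelled shape dataset."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import chisquare

from spineridge.errors import ValidationError
from spineridge.hu_features import hu_of
from spineridge.synthgen import (
    Curve,
    GenerativeParams,
    SpineSpec,
    make_shape_dataset,
    make_tube_params,
    mixture_density,
    random_spine_specs,
    render_image,
    sample_points,
)


class TestCurve:
    def test_segment_endpoints(self):
        c = Curve([[0.0, 0.0], [10.0, 20.0]])
        np.testing.assert_allclose(c.point(0.0), [0, 0])
        np.testing.assert_allclose(c.point(1.0), [10, 20])

    def test_bezier_arc_length_exceeds_chord(self):
        c = Curve([[0, 0], [0, 40], [40, 60], [40, 100.0]])
        assert c.arc_length() > np.linalg.norm([40, 100])

    def test_bad_control_points(self):
        with pytest.raises(ValidationError):
            Curve([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])


class TestSamplePoints:
    def test_deterministic(self):
        p = make_tube_params((100, 100))
        a = sample_points(p, 500, seed=3).points
        b = sample_points(p, 500, seed=3).points
        np.testing.assert_array_equal(a, b)

    def test_eta_one_sigma_zero_on_curve(self):
        p = make_tube_params((100, 100))
        p.eta, p.sigma = 1.0, 0.0
        s = sample_points(p, 400, seed=0)
        poly = np.vstack([c.polyline(1000) for c in p.curves])
        d, _ = cKDTree(poly).query(s.points)
        assert d.max() < 0.2

    def test_eta_zero_uniform(self):
        p = make_tube_params((100, 100))
        p.eta = 0.0
        s = sample_points(p, 10000, seed=1)
        qr = (s.points[:, 0] >= 50).astype(int) * 2 + (s.points[:, 1] >= 50)
        counts = np.bincount(qr, minlength=4)
        assert chisquare(counts).pvalue > 0.01

    def test_curve_weight_fraction(self):
        p = make_tube_params((200, 200), kind="parallel")
        p.weights = np.array([0.9, 0.1])
        s = sample_points(p, 10000, seed=2)
        on_curve = s.curve_index >= 0
        frac = (s.curve_index[on_curve] == 0).mean()
        assert frac == pytest.approx(0.9, abs=3 * np.sqrt(0.09 / on_curve.sum()))

    def test_empirical_density_matches_mixture(self):
        p = make_tube_params((128, 128), kind="curved")
        s = sample_points(p, 50000, seed=5)
        H, xe, ye = np.histogram2d(s.points[:, 0], s.points[:, 1],
                                   bins=32, range=[[0, 128], [0, 128]])
        centers_r = 0.5 * (xe[:-1] + xe[1:])
        centers_c = 0.5 * (ye[:-1] + ye[1:])
        rr, cc = np.meshgrid(centers_r, centers_c, indexing="ij")
        grid = np.stack([rr.ravel(), cc.ravel()], axis=1)
        dens = mixture_density(p, grid)
        r = np.corrcoef(H.ravel(), dens)[0, 1]
        assert r >= 0.95


class TestRenderImage:
    def test_deterministic(self):
        p = make_tube_params((128, 128))
        specs = random_spine_specs(p, 4, seed=9)
        a, _ = render_image(p, specs, seed=4)
        b, _ = render_image(p, specs, seed=4)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_noiseless_tube_half_max(self):
        p = make_tube_params((80, 160), kind="straight")
        img, _ = render_image(p, [], tube_halfwidth=3.0, snr=np.inf,
                              sp_noise=0.0, seed=0)
        profile = img.pixels[:, 80]
        row = int(p.curves[0].point(0.5)[0])
        # peak 1 up to centreline-polyline discretization (~0.12 px)
        assert profile[row] == pytest.approx(1.0, abs=0.01)

        def crossing(side):
            # linear interpolation of the half-max crossing on one side
            for k in range(1, 20):
                a, b = profile[row + side * (k - 1)], profile[row + side * k]
                if a >= 0.5 > b:
                    return (k - 1) + (a - 0.5) / (a - b)
            raise AssertionError("no crossing found")

        assert crossing(+1) == pytest.approx(3.0, abs=0.25)
        assert crossing(-1) == pytest.approx(3.0, abs=0.25)

    def test_zero_spines_empty_ground_truth(self):
        p = make_tube_params((64, 64))
        _, gt = render_image(p, [], seed=0)
        assert gt.spine_labels == [] and gt.spine_pixels == []

    def test_invalid_spine_base_rejected(self):
        p = make_tube_params((64, 64))
        spec = SpineSpec(cls="thin", curve_index=3, t=0.5,
                         geometry={"length": 10, "width": 1.5})
        with pytest.raises(ValidationError):
            render_image(p, [spec], seed=0)

    def test_ground_truth_aligned(self):
        p = make_tube_params((200, 200), kind="straight")
        specs = random_spine_specs(p, 6, seed=11)
        img, gt = render_image(p, specs, snr=np.inf, sp_noise=0.0, seed=0)
        assert len(gt.spine_pixels) == 6
        for pix in gt.spine_pixels:
            assert img.pixels[pix[:, 0], pix[:, 1]].min() > 0.5

    def test_clutter_disjoint_from_spines(self):
        p = make_tube_params((420, 420), kind="straight")
        specs = random_spine_specs(p, 5, seed=2, min_spacing_px=18)
        bases = [np.atleast_1d(p.curves[s.curve_index].point(s.t)) for s in specs]
        clut = random_spine_specs(p, 3, seed=7, classes=("pseudo",),
                                  min_spacing_px=18, avoid=bases,
                                  avoid_spacing_px=32)
        _, gt = render_image(p, specs + clut, seed=1)
        spine_mask = gt.spine_mask((420, 420))
        assert not (spine_mask & gt.clutter_mask).any()


class TestShapeDataset:
    def test_counts_and_balance(self):
        imgs, labels, recs = make_shape_dataset(5, seed=3)
        assert len(imgs) == 20
        for cls in ("mushroom", "stubby", "thin", "pseudo"):
            assert labels.count(cls) == 5

    def test_mushroom_head_exceeds_neck(self):
        _, labels, recs = make_shape_dataset(8, seed=4)
        for lab, rec in zip(labels, recs):
            if lab == "mushroom":
                assert rec["head_radius"] > rec["neck_width"]

    def test_thin_h1_exceeds_stubby_h1(self):
        imgs, labels, _ = make_shape_dataset(15, seed=6)
        h1 = {"thin": [], "stubby": []}
        for img, lab in zip(imgs, labels):
            if lab in h1:
                h1[lab].append(hu_of(img.astype(float)).values[0])
        assert np.mean(h1["thin"]) > np.mean(h1["stubby"])

    def test_deterministic(self):
        a, la, _ = make_shape_dataset(3, seed=8)
        b, lb, _ = make_shape_dataset(3, seed=8)
        assert la == lb
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
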