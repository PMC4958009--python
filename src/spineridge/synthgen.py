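"""Synthetic dendrite images with aligned ground truth.

The point-sample generative model: a foreground/background coin with
foreground probability eta; foreground points pick a dendrite curve f_i
with weight w_i, a uniform parameter theta on the curve, and add isotropic
Gaussian noise of scale sigma; background points are uniform clutter on the
image rectangle. The rendered-image counterpart draws each curve as a tube
with a Gaussian cross-section (peak 1, half-max half-width equal to
``tube_halfwidth``), stamps spines of the three morphological classes
(mushroom = disc head on a thin neck, stubby = short wide bump,
thin = long narrow protrusion) plus ragged pseudo-spine blobs on the tube,
and corrupts with Gaussian background noise (amplitude 1/SNR) and
salt-and-pepper noise.

Everything is seeded and bit-reproducible; ground truth (centerlines,
per-spine masks and labels, clutter mask) is emitted aligned with the
image so every pipeline stage has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .density_ridge import SampleSet
from .errors import ValidationError
from .io_preprocess import DEFAULT_PIXEL_SIZE_UM, GrayImage

_SQRT_2LN2 = float(np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# parametric curves

@dataclass
class Curve:
    """Straight segment (2 control points) or cubic Bezier (4 control points),
    parameterized on t in [0, 1]; coordinates are (row, col)."""

    ctrl: np.ndarray

    def __post_init__(self):
        self.ctrl = np.atleast_2d(np.asarray(self.ctrl, dtype=float))
        if self.ctrl.shape not in ((2, 2), (4, 2)):
            raise ValidationError("Curve needs 2 (segment) or 4 (Bezier) control points")

    def point(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        c = self.ctrl
        if c.shape[0] == 2:
            out = (1 - t) * c[0] + t * c[1]
        else:
            out = (
                (1 - t) ** 3 * c[0]
                + 3 * (1 - t) ** 2 * t * c[1]
                + 3 * (1 - t) * t**2 * c[2]
                + t**3 * c[3]
            )
        return out if out.shape[0] > 1 else out[0]

    def tangent(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        c = self.ctrl
        if c.shape[0] == 2:
            d = np.broadcast_to(c[1] - c[0], (t.shape[0], 2)).copy()
        else:
            d = (
                3 * (1 - t) ** 2 * (c[1] - c[0])
                + 6 * (1 - t) * t * (c[2] - c[1])
                + 3 * t**2 * (c[3] - c[2])
            )
        d = d / np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-12)
        return d if d.shape[0] > 1 else d[0]

    def polyline(self, n: int = 200) -> np.ndarray:
        return self.point(np.linspace(0.0, 1.0, n))

    def arc_length(self, n: int = 400) -> float:
        p = self.polyline(n)
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


@dataclass
class GenerativeParams:
    """Mixture parameters of the point-sample model."""

    curves: list
    weights: np.ndarray = None
    eta: float = 0.95
    sigma: float = 2.0
    shape: tuple = (256, 256)

    def __post_init__(self):
        if not self.curves:
            raise ValidationError("need at least one curve")
        if self.weights is None:
            self.weights = np.full(len(self.curves), 1.0 / len(self.curves))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.curves) or (self.weights <= 0).any():
            raise ValidationError("weights must be positive, one per curve")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must sum to 1")
        if not (0.0 <= self.eta <= 1.0):
            raise ValidationError("eta must lie in [0, 1]")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")

    @property
    def volume(self) -> float:
        return float(self.shape[0] * self.shape[1])


@dataclass
class LabeledSamples(SampleSet):
    """SampleSet plus which mixture component generated each point
    (-1 = uniform clutter)."""

    curve_index: np.ndarray = None


def sample_points(params: GenerativeParams, N: int, seed: int = 0) -> LabeledSamples:
    """Draw N points from the mixture model, seeded and reproducible."""
    if N < 1:
        raise ValidationError("N must be >= 1")
    rng = np.random.default_rng(seed)
    H, W = params.shape
    is_fg = rng.random(N) < params.eta
    comp = np.full(N, -1, dtype=int)
    pts = np.empty((N, 2))
    n_bg = int((~is_fg).sum())
    pts[~is_fg, 0] = rng.uniform(0, H, n_bg)
    pts[~is_fg, 1] = rng.uniform(0, W, n_bg)
    n_fg = int(is_fg.sum())
    if n_fg:
        ci = rng.choice(len(params.curves), size=n_fg, p=params.weights)
        comp[is_fg] = ci
        ts = rng.uniform(0.0, 1.0, n_fg)
        fg = np.empty((n_fg, 2))
        for i, curve in enumerate(params.curves):
            sel = ci == i
            if sel.any():
                fg[sel] = np.atleast_2d(curve.point(ts[sel]))
        fg += rng.normal(0.0, params.sigma, size=(n_fg, 2))
        pts[is_fg] = fg
    return LabeledSamples(points=pts, curve_index=comp)


def mixture_density(params: GenerativeParams, X: np.ndarray, n_theta: int = 300) -> np.ndarray:
    """Analytic mixture density of the generative model on points X
    (theta integral discretized on n_theta nodes)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sig2 = max(params.sigma, 1e-6) ** 2
    norm = 1.0 / (2.0 * np.pi * sig2)
    dens = np.zeros(X.shape[0])
    ts = np.linspace(0.0, 1.0, n_theta)
    for w, curve in zip(params.weights, params.curves):
        P = curve.polyline(n_theta)
        d2 = (
            np.sum(X * X, axis=1)[:, None]
            + np.sum(P * P, axis=1)[None, :]
            - 2.0 * X @ P.T
        )
        dens += w * norm * np.exp(-np.maximum(d2, 0) / (2 * sig2)).mean(axis=1)
    return params.eta * dens + (1.0 - params.eta) / params.volume


# ---------------------------------------------------------------------------
# spine specs and drawing helpers

SPINE_CLASSES = ("mushroom", "stubby", "thin")
ALL_CLASSES = SPINE_CLASSES + ("pseudo",)


@dataclass
class SpineSpec:
    """One planted spine: class, base location on a curve, geometry (px)."""

    cls: str
    curve_index: int
    t: float
    side: int = 1
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cls not in ALL_CLASSES:
            raise ValidationError(f"unknown spine class {self.cls!r}")
        if not (0.0 <= self.t <= 1.0):
            raise ValidationError("t must lie in [0, 1]")
        if self.side not in (-1, 1):
            raise ValidationError("side must be +1 or -1")


def _sample_geometry(cls: str, rng) -> dict:
    # ranges sized for ~0.5-2 µm spines at 0.24 µm/px
    if cls == "thin":
        width = rng.uniform(1.0, 2.0)
        # real thin spines bend mildly; total turn stays well below the
        # strong consistent curl of the pseudo class
        return {"length": rng.uniform(8.0, 20.0), "width": width,
                "curvature": float(rng.uniform(-0.03, 0.03))}
    if cls == "stubby":
        width = rng.uniform(3.0, 6.0)
        return {"length": rng.uniform(2.0, min(5.0, 1.5 * width)), "width": width}
    if cls == "mushroom":
        neck_w = rng.uniform(1.0, 2.0)
        head_r = rng.uniform(max(3.0, neck_w + 0.5), 6.0)
        return {
            "neck_length": rng.uniform(3.0, 8.0),
            "neck_width": neck_w,
            "head_radius": head_r,
        }
    # pseudo: gently but consistently curling open chain of small discs
    # (membrane fragments / texture noise). The steady curvature keeps it
    # from straightening into a thin-spine impostor, while the gentle turn
    # rate keeps it an open arc that cannot ball up into a stubby- or
    # mushroom-like solid blob under the mask smoothing.
    curl = float(rng.choice([-1.0, 1.0]))
    n_blobs = int(rng.integers(6, 10))
    # total turn makes an open "C": strongly curved relative to any thin
    # spine, but never enough to close into a compact blob
    total_turn = curl * rng.uniform(1.8, 3.0)
    inc = np.full(n_blobs, total_turn / n_blobs)
    inc = inc * rng.uniform(0.7, 1.3, n_blobs)
    return {
        "n_blobs": n_blobs,
        "radii": rng.uniform(0.8, 1.5, size=n_blobs).tolist(),
        "spread": rng.uniform(2.0, 4.0),
        "step": rng.uniform(3.0, 4.0),
        "turns": inc.cumsum().tolist(),
        "branch_at": int(rng.integers(0, 3)),
        "branch_turns": (-curl * rng.uniform(0.3, 0.5, size=4)).cumsum().tolist(),
        "n_branch": int(rng.integers(0, 3)),
    }


def random_spine_specs(
    params: GenerativeParams,
    n: int,
    seed: int = 0,
    classes=SPINE_CLASSES,
    t_range=(0.06, 0.94),
    min_spacing_px: float = 12.0,
    avoid=None,
    avoid_spacing_px: float | None = None,
):
    """n well-spaced spine specs with class-conditional random geometry.

    ``avoid`` is an optional list of base points (e.g. of already placed
    spines) that new bases must clear by ``avoid_spacing_px``
    (default: ``min_spacing_px``).
    """
    rng = np.random.default_rng(seed)
    if avoid_spacing_px is None:
        avoid_spacing_px = min_spacing_px
    lengths = np.array([c.arc_length() for c in params.curves])
    probs = lengths / lengths.sum()
    specs = []
    bases = []
    avoid_pts = np.asarray([np.asarray(b, dtype=float) for b in (avoid or [])])
    attempts = 0
    while len(specs) < n and attempts < 200 * n:
        attempts += 1
        ci = int(rng.choice(len(params.curves), p=probs))
        t = float(rng.uniform(*t_range))
        base = np.atleast_1d(params.curves[ci].point(t))
        if bases and min(
            np.linalg.norm(np.asarray(bases) - base, axis=1)
        ) < min_spacing_px:
            continue
        if avoid_pts.size and np.linalg.norm(
            avoid_pts - base, axis=1
        ).min() < avoid_spacing_px:
            continue
        cls = classes[len(specs) % len(classes)]
        side = 1 if len(specs) % 2 == 0 else -1
        specs.append(
            SpineSpec(cls=cls, curve_index=ci, t=t, side=side,
                      geometry=_sample_geometry(cls, rng))
        )
        bases.append(base)
    if len(specs) < n:
        raise ValidationError("could not place spines with requested spacing")
    return specs


def _capsule_pixels(shape, p0, p1, width):
    """Integer pixels within width/2 of segment p0-p1."""
    H, W = shape
    rad = width / 2.0
    lo = np.floor(np.minimum(p0, p1) - rad - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + rad + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, [H - 1, W - 1])
    if (hi < lo).any():
        return np.empty((0, 2), dtype=int)
    rr, cc = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    P = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    v = p1 - p0
    L2 = float(v @ v)
    if L2 < 1e-12:
        d = np.linalg.norm(P - p0, axis=1)
    else:
        u = np.clip((P - p0) @ v / L2, 0.0, 1.0)
        d = np.linalg.norm(P - (p0 + u[:, None] * v), axis=1)
    return P[d <= rad].astype(int)


def _disc_pixels(shape, center, radius):
    return _capsule_pixels(shape, np.asarray(center, float),
                           np.asarray(center, float), 2.0 * radius)


def spine_pixels(spec: SpineSpec, base, normal, shape, root_offset: float = 0.0,
                 rng=None) -> np.ndarray:
    """Full-image integer pixels of one spine stamped at ``base`` along
    ``normal``; the skeleton starts ``root_offset`` px along the normal
    (the tube half-width, so the protrusion beyond the boundary has the
    nominal length)."""
    base = np.asarray(base, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / max(np.linalg.norm(normal), 1e-12)
    g = spec.geometry
    # diffraction floor: nothing images narrower than ~1.5 px at this
    # pixel pitch, and a sub-pixel-width capsule would rasterize into a
    # broken pixel chain no microscope produces
    PSF_FLOOR = 1.5
    if spec.cls in ("thin", "stubby"):
        curv = g.get("curvature", 0.0)
        width = max(g["width"], PSF_FLOOR)
        if abs(curv) < 1e-6:
            tip = base + (root_offset + g["length"]) * normal
            return _capsule_pixels(shape, base, tip, width)
        # mildly bent protrusion: chain of short capsules along an arc
        perp = np.array([-normal[1], normal[0]])
        seg = 2.0
        n_seg = max(1, int(np.ceil((root_offset + g["length"]) / seg)))
        pix = []
        p = base.copy()
        ang = 0.0
        for _ in range(n_seg):
            d = np.cos(ang) * normal + np.sin(ang) * perp
            q = p + seg * d
            pix.append(_capsule_pixels(shape, p, q, width))
            p = q
            ang += curv * seg
        allp = np.vstack([x for x in pix if x.size])
        if allp.size == 0:
            return allp.reshape(0, 2)
        return np.unique(allp, axis=0)
    if spec.cls == "mushroom":
        neck_end = base + (root_offset + g["neck_length"]) * normal
        head_c = neck_end + 0.8 * g["head_radius"] * normal
        neck = _capsule_pixels(shape, base, neck_end,
                               max(g["neck_width"], PSF_FLOOR))
        head = _disc_pixels(shape, head_c, g["head_radius"])
        both = np.vstack([neck, head])
        return np.unique(both, axis=0)
    # pseudo: snaky chain of small discs, optionally branched
    rng = rng or np.random.default_rng(abs(hash((spec.curve_index, round(spec.t, 6)))) % (2**31))
    perp = np.array([-normal[1], normal[0]])
    c = base + (root_offset + g["spread"]) * normal
    pix = [_capsule_pixels(shape, base, c, 1.2)]  # thin ragged stalk
    turns = g.get("turns") or [0.0]
    step = g.get("step", 3.0)
    radii = g["radii"]
    chain = []
    for k in range(g["n_blobs"]):
        pix.append(_disc_pixels(shape, c, radii[k % len(radii)]))
        chain.append(c)
        ang = turns[k % len(turns)]
        d = np.cos(ang) * normal + np.sin(ang) * perp
        nxt = c + step * d
        pix.append(_capsule_pixels(shape, c, nxt, 1.5))
        c = nxt
    n_branch = int(g.get("n_branch", 0))
    if n_branch and chain:
        b = chain[min(g.get("branch_at", 0), len(chain) - 1)]
        bturns = g.get("branch_turns") or [1.2]
        for k in range(n_branch):
            ang = bturns[k % len(bturns)] + np.pi / 2.0
            nxt = b + step * (np.cos(ang) * normal + np.sin(ang) * perp)
            pix.append(_capsule_pixels(shape, b, nxt, 1.5))
            pix.append(_disc_pixels(shape, nxt, radii[k % len(radii)]))
            b = nxt
    allp = np.vstack([p for p in pix if p.size])
    if allp.size == 0:
        return allp.reshape(0, 2)
    return np.unique(allp, axis=0)


@dataclass
class GroundTruth:
    """Everything the tests need to score the pipeline."""

    centerlines: list                 # (M,2) arrays, one per curve
    spine_pixels: list                # (K,2) int arrays (true spines)
    spine_labels: list
    spine_bases: list                 # boundary-side base points
    clutter_pixels: list              # pseudo-spine pixel arrays
    dendrite_mask: np.ndarray         # tube core (dist <= halfwidth)
    clutter_mask: np.ndarray

    def spine_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        for p in self.spine_pixels:
            m[p[:, 0], p[:, 1]] = True
        return m


def render_image(
    params: GenerativeParams,
    spines,
    tube_halfwidth: float = 3.0,
    snr: float = 10.0,
    sp_noise: float = 0.01,
    seed: int = 0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
):
    """Render the generative model to a noisy grayscale image + ground truth."""
    if tube_halfwidth <= 0:
        raise ValidationError("tube_halfwidth must be positive")
    if snr <= 0:
        raise ValidationError("snr must be positive")
    if not (0.0 <= sp_noise < 1.0):
        raise ValidationError("sp_noise must lie in [0, 1)")
    for s in spines:
        if not (0 <= s.curve_index < len(params.curves)):
            raise ValidationError("spine base not on any curve")
    H, W = params.shape
    rng = np.random.default_rng(seed)
    s_gauss = tube_halfwidth / _SQRT_2LN2

    # tube profile from distance to densely sampled centerlines
    centerlines = []
    grid_r, grid_c = np.mgrid[0:H, 0:W]
    grid = np.stack([grid_r.ravel(), grid_c.ravel()], axis=1).astype(float)
    from scipy.spatial import cKDTree

    all_cl = []
    for curve in params.curves:
        n = max(64, int(4 * curve.arc_length()))
        cl = curve.polyline(n)
        centerlines.append(cl)
        all_cl.append(cl)
    tree = cKDTree(np.vstack(all_cl))
    d, _ = tree.query(grid, workers=-1)
    d = d.reshape(H, W)
    img = np.exp(-(d**2) / (2.0 * s_gauss**2))
    dendrite_core = d <= tube_halfwidth

    # spines
    spine_pix, spine_labels, spine_bases, clutter_pix = [], [], [], []
    union = np.zeros((H, W), dtype=bool)
    clutter_mask = np.zeros((H, W), dtype=bool)
    for spec in spines:
        curve = params.curves[spec.curve_index]
        base = np.atleast_1d(curve.point(spec.t))
        tang = np.atleast_1d(curve.tangent(spec.t))
        normal = np.array([-tang[1], tang[0]]) * spec.side
        pix = spine_pixels(spec, base, normal, (H, W),
                           root_offset=tube_halfwidth, rng=rng)
        if pix.size == 0:
            continue
        union[pix[:, 0], pix[:, 1]] = True
        boundary_base = base + tube_halfwidth * normal
        if spec.cls == "pseudo":
            clutter_pix.append(pix)
            clutter_mask[pix[:, 0], pix[:, 1]] = True
        else:
            spine_pix.append(pix)
            spine_labels.append(spec.cls)
            spine_bases.append(boundary_base)
    if union.any():
        d_out = ndimage.distance_transform_edt(~union)
        soft = np.exp(-(d_out**2) / (2.0 * 0.6**2))
        img = np.maximum(img, soft)

    # noise
    if np.isfinite(snr):
        img = img + rng.normal(0.0, 1.0 / snr, size=(H, W))
    n_sp = int(round(sp_noise * H * W))
    if n_sp:
        idx = rng.choice(H * W, size=n_sp, replace=False)
        salt = idx[: n_sp // 2]
        pepper = idx[n_sp // 2 :]
        flat = img.ravel()
        flat[salt] = 1.0
        flat[pepper] = 0.0
        img = flat.reshape(H, W)
    np.clip(img, 0.0, 1.0, out=img)

    gt = GroundTruth(
        centerlines=centerlines,
        spine_pixels=spine_pix,
        spine_labels=spine_labels,
        spine_bases=spine_bases,
        clutter_pixels=clutter_pix,
        dendrite_mask=dendrite_core,
        clutter_mask=clutter_mask,
    )
    return GrayImage(img, pixel_size_um=pixel_size_um), gt


# ---------------------------------------------------------------------------
# canonical tube layouts for tests and the acceptance suite

def make_tube_params(shape=(200, 200), kind: str = "straight",
                     eta: float = 0.95, sigma: float = 2.0) -> GenerativeParams:
    """Canonical layouts: 'straight', 'curved' (Bezier), 'y' (branched),
    'parallel' (two tubes 40 px apart)."""
    H, W = shape
    m = 20.0
    if kind == "straight":
        curves = [Curve([[H / 2.0, m], [H / 2.0, W - m]])]
    elif kind == "curved":
        curves = [
            Curve(
                [
                    [H - m, m],
                    [H * 0.25, W * 0.35],
                    [H * 0.75, W * 0.65],
                    [m, W - m],
                ]
            )
        ]
    elif kind == "y":
        curves = [
            Curve([[H / 2.0, m], [H / 2.0, W - m]]),
            Curve([[H / 2.0, W / 2.0], [m, W - m]]),
        ]
    elif kind == "parallel":
        curves = [
            Curve([[H / 2.0 - 20.0, m], [H / 2.0 - 20.0, W - m]]),
            Curve([[H / 2.0 + 20.0, m], [H / 2.0 + 20.0, W - m]]),
        ]
    else:
        raise ValidationError(f"unknown layout {kind!r}")
    n = len(curves)
    return GenerativeParams(curves=curves, weights=np.full(n, 1.0 / n),
                            eta=eta, sigma=sigma, shape=shape)


# ---------------------------------------------------------------------------
# labelled shape dataset for classifier training

def _rendered_shape(cls: str, geometry: dict, rng, canvas: int = 64,
                    tube_halfwidth: float = 3.0, snr: float = 10.0,
                    sp_noise: float = 0.01):
    """Render one spine on a miniature tube and extract the binary region
    exactly as the detection stage would see it (threshold, lenient
    majority vote, dendrite subtraction, closing, connected component)."""
    from scipy import ndimage as _ndi

    from .io_preprocess import binarize, majority, otsu_threshold

    row = canvas * 0.68
    params = GenerativeParams(
        curves=[Curve([[row, 2.0], [row, canvas - 2.0]])],
        weights=np.array([1.0]), eta=1.0, sigma=1.0, shape=(canvas, canvas),
    )
    spec = SpineSpec(cls=cls, curve_index=0,
                     t=float(rng.uniform(0.45, 0.55)), side=-1,
                     geometry=geometry)
    img, _ = render_image(params, [spec], tube_halfwidth=tube_halfwidth,
                          snr=snr, sp_noise=sp_noise,
                          seed=int(rng.integers(2**31)))
    thr = min(max(otsu_threshold(img), 1e-6), 1 - 1e-6)
    spmask = majority(binarize(img, "fixed", thr), 2).pixels
    # analytic dendrite band: the tube is straight and horizontal; the
    # extra cut depth is randomized so the classifier sees the full range
    # of root truncations the deployed dendrite subtraction produces
    s_gauss = tube_halfwidth / _SQRT_2LN2
    hw = s_gauss * np.sqrt(2.0 * np.log(1.0 / thr)) + float(rng.uniform(1.0, 2.5))
    # per-column jitter emulates the marched boundary's sub-pixel noise
    hw_cols = hw + rng.uniform(-0.4, 0.4, size=canvas)
    rows = np.arange(canvas, dtype=float)[:, None]
    dend = np.abs(rows - row) <= hw_cols[None, :]
    outside = spmask & ~dend
    outside = _ndi.binary_closing(outside, structure=np.ones((3, 3))) & ~dend
    labels_arr, n = _ndi.label(outside, structure=np.ones((3, 3)))
    if n == 0:
        return None
    sizes = _ndi.sum_labels(np.ones_like(labels_arr), labels_arr,
                            index=np.arange(1, n + 1))
    pix = np.argwhere(labels_arr == (1 + int(np.argmax(sizes))))
    if pix.shape[0] < 4:
        return None
    out = np.zeros((canvas, canvas), dtype=bool)
    out[pix[:, 0], pix[:, 1]] = True
    return out


def make_shape_dataset(n_per_class: int, seed: int = 0, canvas: int = 64):
    """Balanced, seeded binary shape images for the four classes
    (mushroom, stubby, thin, pseudo).

    Each shape is rendered on a miniature dendrite tube with noise and
    pushed through the same thresholding / majority / dendrite-subtraction
    chain the detection stage applies, so the classifier trains on the
    distribution it will be deployed on. Returns (images, labels, records);
    each record stores the sampled geometry so class invariants can be
    audited.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels, records = [], [], []
    for cls in ALL_CLASSES:
        made = 0
        while made < n_per_class:
            g = _sample_geometry(cls, rng)
            img = _rendered_shape(cls, g, rng, canvas=canvas,
                                  snr=float(rng.uniform(8.0, 15.0)))
            if img is None:
                continue
            images.append(img)
            labels.append(cls)
            records.append({"class": cls, **g})
            made += 1
    return images, labels, records
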