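"""Dendrite boundary location by perpendicular intensity marching.

From every backbone point the local line direction is taken from the
Gaussian-smoothed image Hessian (eigenvector with the smallest-magnitude
second derivative); marching perpendicular to it in subpixel steps with
bilinear interpolation, the boundary is the last position whose intensity
is still >= alpha before it first drops below alpha. The per-point width
is the distance between the left and right boundary crossings, in
micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon
from skimage.filters import threshold_otsu

from .density_ridge import BackboneGraph
from .errors import ValidationError
from .io_preprocess import BinaryMask, GrayImage


@dataclass
class DendriteBoundary:
    """Per-backbone-point left/right boundary crossings and widths.

    ``flags`` marks points where the backbone intensity itself was below
    alpha (width undefined, NaN). ``curve_index`` maps each row to the
    backbone curve it came from so the mask fill can stay per-curve.
    """

    backbone_points: np.ndarray
    left: np.ndarray
    right: np.ndarray
    widths_um: np.ndarray
    alpha: float
    curve_index: np.ndarray = field(default=None)

    def __post_init__(self):
        n = self.backbone_points.shape[0]
        if not (self.left.shape[0] == self.right.shape[0] == n):
            raise ValidationError("left/right must match backbone point count")
        if self.curve_index is None:
            self.curve_index = np.zeros(n, dtype=int)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.widths_um)

    def to_dict(self, pixel_size_um: float) -> dict:
        return {
            "alpha": self.alpha,
            "left_px": self.left.tolist(),
            "right_px": self.right.tolist(),
            "widths_um": [None if np.isnan(w) else w for w in self.widths_um],
            "curve_index": self.curve_index.tolist(),
            "pixel_size_um": pixel_size_um,
        }


def _hessian_fields(pixels: np.ndarray, sigma_d: float):
    Irr = ndimage.gaussian_filter(pixels, sigma_d, order=(2, 0), mode="reflect")
    Icc = ndimage.gaussian_filter(pixels, sigma_d, order=(0, 2), mode="reflect")
    Irc = ndimage.gaussian_filter(pixels, sigma_d, order=(1, 1), mode="reflect")
    return Irr, Irc, Icc


def _interp(field: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        field, [pts[:, 0], pts[:, 1]], order=1, mode="nearest"
    )


def local_direction(
    img: GrayImage,
    p,
    sigma_d: float = 2.0,
    return_degenerate: bool = False,
):
    """Local line tangent at point p from the smoothed Hessian.

    Returns the unit eigenvector of the Gaussian-scale image Hessian with
    the smallest absolute eigenvalue (the along-line direction), sign-fixed
    to an angle in [0, 180). With ``return_degenerate=True`` also returns
    whether the eigenvalues were too close to tell line from blob.
    """
    p = np.asarray(p, dtype=float)
    if sigma_d <= 0:
        raise ValidationError("sigma_d must be positive")
    if not (0 <= p[0] <= img.height - 1 and 0 <= p[1] <= img.width - 1):
        raise ValidationError("point outside image")
    Irr, Irc, Icc = _hessian_fields(img.pixels, sigma_d)
    pt = p[None, :]
    H = np.array(
        [
            [_interp(Irr, pt)[0], _interp(Irc, pt)[0]],
            [_interp(Irc, pt)[0], _interp(Icc, pt)[0]],
        ]
    )
    evals, evecs = np.linalg.eigh(H)
    k = int(np.argmin(np.abs(evals)))
    t = evecs[:, k]
    degenerate = abs(abs(evals[0]) - abs(evals[1])) <= 0.1 * (
        abs(evals[0]) + abs(evals[1]) + 1e-12
    )
    # canonical sign: angle in [0, 180) over (row, col) axes
    if t[1] < 0 or (t[1] == 0 and t[0] < 0):
        t = -t
    if return_degenerate:
        return t, degenerate
    return t


def _march_widths(pixels, points, normals, alpha, max_halfwidth, step=0.25):
    """Half-widths on both sides of each point along its unit normal.

    The crossing is refined by linear interpolation between the last
    sample >= alpha and the first below, removing the half-step bias of
    the raw march grid.
    """
    n_steps = int(np.floor(max_halfwidth / step))
    ts = step * np.arange(0, n_steps + 1)        # include the centre
    halves = np.empty((2, points.shape[0]))
    for side, sgn in enumerate((1.0, -1.0)):
        # (P, S, 2) sample positions
        pos = points[:, None, :] + sgn * ts[None, :, None] * normals[:, None, :]
        vals = ndimage.map_coordinates(
            pixels,
            [pos[..., 0].ravel(), pos[..., 1].ravel()],
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(points.shape[0], ts.size)
        below = vals < alpha
        first_below = np.where(below.any(axis=1), below.argmax(axis=1), ts.size)
        h = np.empty(points.shape[0])
        for i, k in enumerate(first_below):
            if k >= ts.size:                     # never dropped: cap
                h[i] = max_halfwidth
            elif k == 0:                         # centre already below alpha
                h[i] = 0.0
            else:
                v0, v1 = vals[i, k - 1], vals[i, k]
                frac = (v0 - alpha) / max(v0 - v1, 1e-12)
                h[i] = min(ts[k - 1] + np.clip(frac, 0.0, 1.0) * step,
                           max_halfwidth)
        halves[side] = h
    return halves


def locate_boundary(
    img: GrayImage,
    backbone: BackboneGraph,
    alpha: float,
    max_halfwidth: float = 20.0,
    sigma_d: float = 2.0,
    step: float = 0.25,
) -> DendriteBoundary:
    """March perpendicular to the local line direction from each backbone
    point until intensity first drops below alpha; record both crossings.

    Points whose own interpolated intensity is already below alpha are
    flagged (NaN width). Degenerate Hessian directions fall back to the
    backbone polyline tangent.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    if max_halfwidth <= 0:
        raise ValidationError("max_halfwidth must be positive")
    pts_list, tan_list, idx_list = [], [], []
    for ci, curve in enumerate(backbone.curves):
        P = curve.points
        if P.shape[0] < 2:
            continue
        T = np.gradient(P, axis=0)
        T /= np.maximum(np.linalg.norm(T, axis=1, keepdims=True), 1e-12)
        pts_list.append(P)
        tan_list.append(T)
        idx_list.append(np.full(P.shape[0], ci))
    if not pts_list:
        raise ValidationError("backbone has no usable curves")
    points = np.vstack(pts_list)
    poly_tan = np.vstack(tan_list)
    curve_index = np.concatenate(idx_list)

    Irr, Irc, Icc = _hessian_fields(img.pixels, sigma_d)
    a = _interp(Irr, points)
    b = _interp(Irc, points)
    c = _interp(Icc, points)
    tangents = np.empty_like(points)
    for i in range(points.shape[0]):
        H = np.array([[a[i], b[i]], [b[i], c[i]]])
        evals, evecs = np.linalg.eigh(H)
        if abs(abs(evals[0]) - abs(evals[1])) <= 0.1 * (
            abs(evals[0]) + abs(evals[1]) + 1e-12
        ):
            tangents[i] = poly_tan[i]          # degenerate: backbone tangent
        else:
            tangents[i] = evecs[:, int(np.argmin(np.abs(evals)))]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)

    center_I = ndimage.map_coordinates(
        img.pixels, [points[:, 0], points[:, 1]], order=1, mode="constant"
    )
    halves = _march_widths(img.pixels, points, normals, alpha, max_halfwidth, step)
    left = points + halves[0][:, None] * normals
    right = points - halves[1][:, None] * normals
    widths = (halves[0] + halves[1]) * img.pixel_size_um
    widths[center_I < alpha] = np.nan
    return DendriteBoundary(
        backbone_points=points,
        left=left,
        right=right,
        widths_um=widths,
        alpha=alpha,
        curve_index=curve_index,
    )


def suggest_alpha(img: GrayImage, backbone: BackboneGraph, sigma_d: float = 2.0,
                  max_halfwidth: float = 20.0) -> float:
    """Default alpha: Otsu threshold of intensities sampled along the
    backbone's perpendicular profiles."""
    pts_list, tan_list = [], []
    for curve in backbone.curves:
        P = curve.points
        if P.shape[0] < 2:
            continue
        T = np.gradient(P, axis=0)
        T /= np.maximum(np.linalg.norm(T, axis=1, keepdims=True), 1e-12)
        pts_list.append(P)
        tan_list.append(T)
    if not pts_list:
        return 0.5
    points = np.vstack(pts_list)
    tangents = np.vstack(tan_list)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    ts = np.linspace(-max_halfwidth, max_halfwidth, 41)
    pos = points[:, None, :] + ts[None, :, None] * normals[:, None, :]
    vals = ndimage.map_coordinates(
        img.pixels, [pos[..., 0].ravel(), pos[..., 1].ravel()],
        order=1, mode="constant", cval=0.0,
    )
    if vals.max() - vals.min() < 1e-12:
        return 0.5
    return float(threshold_otsu(vals, nbins=256))


def cap_boundary(bnd: DendriteBoundary, slack_px: float = 0.5) -> DendriteBoundary:
    """Clip each ray's half-width at the per-curve median + ``slack_px``.

    Rays that march through an attached spine (whose intensity never drops
    below alpha along the ray) report outlier half-widths; since dendrite
    caliber varies smoothly, capping at a robust per-curve estimate keeps
    attached protrusions outside the dendrite region.
    """
    pts = bnd.backbone_points
    new_left = bnd.left.copy()
    new_right = bnd.right.copy()
    widths = bnd.widths_um.copy()
    for ci in np.unique(bnd.curve_index):
        sel = (bnd.curve_index == ci) & bnd.valid
        if not sel.any():
            continue
        for side, arr in (("L", new_left), ("R", new_right)):
            v = arr[sel] - pts[sel]
            d = np.linalg.norm(v, axis=1)
            cap = float(np.median(d)) + slack_px
            over = d > cap
            if over.any():
                unit = v[over] / d[over][:, None]
                capped = pts[sel][over] + cap * unit
                tmp = arr[sel]
                tmp[over] = capped
                arr[sel] = tmp
    # widths_um are left as marched (the cap serves mask construction,
    # not the reported morphometry)
    return DendriteBoundary(
        backbone_points=pts,
        left=new_left,
        right=new_right,
        widths_um=widths,
        alpha=bnd.alpha,
        curve_index=bnd.curve_index,
    )


def expand_boundary(bnd: DendriteBoundary, margin: float) -> DendriteBoundary:
    """Push both boundary rails ``margin`` px further out along their march
    normals (used to build a slightly generous dendrite mask whose edge
    covers binarization slivers)."""
    def push(side):
        v = side - bnd.backbone_points
        n = np.linalg.norm(v, axis=1, keepdims=True)
        unit = np.where(n > 1e-9, v / np.maximum(n, 1e-9), 0.0)
        return side + margin * unit

    return DendriteBoundary(
        backbone_points=bnd.backbone_points,
        left=push(bnd.left),
        right=push(bnd.right),
        widths_um=bnd.widths_um,
        alpha=bnd.alpha,
        curve_index=bnd.curve_index,
    )


def dendrite_tube_mask(shape, bnd: DendriteBoundary, margin: float = 0.75,
                       smooth: int = 15) -> BinaryMask:
    """Distance-field dendrite mask from per-point half-widths.

    A pixel belongs to the dendrite iff its distance to the nearest
    backbone point is at most that point's (side-resolved, median-smoothed)
    half-width plus ``margin``. Unlike the quad-fill polygon this has no
    rasterization slivers along the rails, so it is the mask of choice for
    subtracting the dendrite before spine detection.
    """
    from scipy.spatial import cKDTree

    pts = bnd.backbone_points
    if pts.shape[0] == 0:
        return BinaryMask(np.zeros(shape, dtype=bool))
    hw_l = np.linalg.norm(bnd.left - pts, axis=1)
    hw_r = np.linalg.norm(bnd.right - pts, axis=1)
    if smooth > 1:
        k = smooth
        for ci in np.unique(bnd.curve_index):
            sel = np.flatnonzero(bnd.curve_index == ci)
            for hw in (hw_l, hw_r):
                v = hw[sel]
                sm = np.array([
                    np.median(v[max(0, i - k // 2): i + k // 2 + 1])
                    for i in range(v.size)
                ])
                hw[sel] = sm
    normals = bnd.left - pts
    nn = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(nn > 1e-9, normals / np.maximum(nn, 1e-9), normals)
    rmax = float(max(hw_l.max(initial=0), hw_r.max(initial=0))) + margin + 1.0
    H, W = shape
    grid_r, grid_c = np.mgrid[0:H, 0:W]
    grid = np.stack([grid_r.ravel(), grid_c.ravel()], axis=1).astype(float)
    tree = cKDTree(pts)
    d, idx = tree.query(grid, distance_upper_bound=rmax, workers=-1)
    ok = np.isfinite(d)
    out = np.zeros(H * W, dtype=bool)
    gi = np.flatnonzero(ok)
    pi = idx[ok]
    side = np.einsum("ij,ij->i", grid[gi] - pts[pi], normals[pi]) >= 0
    lim = np.where(side, hw_l[pi], hw_r[pi]) + margin
    out[gi] = d[ok] <= lim
    return BinaryMask(out.reshape(H, W))


def dendrite_mask(shape, bnd: DendriteBoundary) -> BinaryMask:
    """Fill the region between consecutive left/right boundary points.

    Quads are built per curve between consecutive valid points; the result
    is clipped to the image domain.
    """
    out = np.zeros(shape, dtype=bool)
    if bnd.backbone_points.shape[0] == 0:
        return BinaryMask(out)
    valid = bnd.valid
    for ci in np.unique(bnd.curve_index):
        sel = np.flatnonzero((bnd.curve_index == ci) & valid)
        for i, j in zip(sel[:-1], sel[1:]):
            if j != i + 1:
                continue
            quad_r = [bnd.left[i, 0], bnd.left[j, 0], bnd.right[j, 0], bnd.right[i, 0]]
            quad_c = [bnd.left[i, 1], bnd.left[j, 1], bnd.right[j, 1], bnd.right[i, 1]]
            rr, cc = polygon(quad_r, quad_c, shape=shape)
            out[rr, cc] = True
    return BinaryMask(out)
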