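"""Dendrite backbone extraction as density ridges of a KDE.

Foreground pixels of the binary image are treated as samples from a mixture
of tube-supported Gaussians plus uniform clutter; the backbone is the
one-dimensional ridge of the Gaussian kernel density estimate built from
those samples. Modes are found by mean-shift ascent, ridge curves are traced
from each mode by a predictor-corrector scheme (predictor along the
weak-curvature Hessian eigenvector, corrector by subspace-constrained mean
shift), low-density points are cut at a threshold theta, and spur branches
created by attached spines are pruned by angular continuity at junctions.

All coordinates are (row, col), subpixel; everything is deterministic given
the mask and the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConvergenceError, ValidationError
from .io_preprocess import BinaryMask


@dataclass
class SampleSet:
    """2-D sample coordinates (row, col) feeding the KDE."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0 or self.points.shape[1] != 2:
            raise ValidationError("SampleSet needs an (N, 2) array with N >= 1")


class KDE:
    """Gaussian kernel density estimate with SPD bandwidth matrix H.

    D(x) = (1/N) sum_i K_H(x - y_i),
    K_H(u) = exp(-u^T H^-1 u / 2) / (2 pi sqrt(det H)).
    """

    def __init__(self, samples, bandwidth):
        if isinstance(samples, SampleSet):
            samples = samples.points
        self.samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if np.isscalar(bandwidth):
            H = float(bandwidth) ** 2 * np.eye(2)
        else:
            H = np.asarray(bandwidth, dtype=float)
        if H.shape != (2, 2) or not np.allclose(H, H.T, atol=1e-12):
            raise ValidationError("bandwidth H must be symmetric 2x2")
        evals = np.linalg.eigvalsh(H)
        if evals.min() <= 0:
            raise ValidationError("bandwidth H must be positive definite")
        self.H = H
        self.Hinv = np.linalg.inv(H)
        self.N = self.samples.shape[0]
        self._norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(H)))
        # characteristic length used for convergence scales
        self.h = float(np.sqrt(evals.min()))

    # -- kernel weights at a single point --------------------------------
    def _weights(self, x):
        u = self.samples - x                      # (N, 2)
        q = np.einsum("ni,ij,nj->n", u, self.Hinv, u)
        return np.exp(-0.5 * q), u

    def density(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            w, _ = self._weights(x)
            return float(self._norm * w.sum() / self.N)
        return np.array([self.density(p) for p in x])

    def density_batch(self, X, chunk: int = 512) -> np.ndarray:
        """Densities at many points, chunked to bound memory."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        for s in range(0, X.shape[0], chunk):
            xb = X[s : s + chunk]
            u = xb[:, None, :] - self.samples[None, :, :]
            q = np.einsum("mni,ij,mnj->mn", u, self.Hinv, u)
            out[s : s + chunk] = self._norm * np.exp(-0.5 * q).sum(axis=1) / self.N
        return out

    def gradient(self, x) -> np.ndarray:
        w, u = self._weights(np.asarray(x, dtype=float))
        return self._norm / self.N * (self.Hinv @ (w @ u))

    def hessian(self, x) -> np.ndarray:
        w, u = self._weights(np.asarray(x, dtype=float))
        S = (u * w[:, None]).T @ u                # sum w_i u_i u_i^T
        return self._norm / self.N * (
            self.Hinv @ S @ self.Hinv - w.sum() * self.Hinv
        )

    def mean_shift(self, x) -> np.ndarray:
        """Kernel-weighted mean of the samples at x (one ascent step)."""
        w, _ = self._weights(np.asarray(x, dtype=float))
        tot = w.sum()
        if tot <= 1e-300:
            return np.asarray(x, dtype=float)
        return (w @ self.samples) / tot

    def mean_shift_batch(self, X, chunk: int = 512) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        for s in range(0, X.shape[0], chunk):
            xb = X[s : s + chunk]
            u = xb[:, None, :] - self.samples[None, :, :]
            q = np.einsum("mni,ij,mnj->mn", u, self.Hinv, u)
            w = np.exp(-0.5 * q)
            tot = w.sum(axis=1)
            safe = tot > 1e-300
            out[s : s + chunk] = np.where(
                safe[:, None], (w @ self.samples) / np.maximum(tot, 1e-300)[:, None], xb
            )
        return out


def kde_evaluate(kde: KDE, x) -> float:
    """Density of the KDE at point x (row, col)."""
    return kde.density(x)


@dataclass
class RidgeCurve:
    """Ordered subpixel ridge points with the density at each point."""

    points: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float)).reshape(-1, 2)
        self.density = np.asarray(self.density, dtype=float).reshape(-1)

    def __len__(self):
        return self.points.shape[0]

    def arc_length(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class BackboneGraph:
    """Collection of ridge curves with junction bookkeeping."""

    curves: list
    theta: float = 0.0
    junctions: list = field(default_factory=list)

    def total_length_px(self) -> float:
        return sum(c.arc_length() for c in self.curves)

    def all_points(self) -> np.ndarray:
        if not self.curves:
            return np.empty((0, 2))
        return np.vstack([c.points for c in self.curves])

    def to_dict(self, pixel_size_um: float = 1.0) -> dict:
        return {
            "theta": self.theta,
            "pixel_size_um": pixel_size_um,
            "curves": [
                {
                    "points_px": c.points.tolist(),
                    "points_um": (c.points * pixel_size_um).tolist(),
                    "density": c.density.tolist(),
                }
                for c in self.curves
            ],
            "junctions": [list(map(float, j)) for j in self.junctions],
        }


# ---------------------------------------------------------------------------
# mode finding

def find_modes(
    kde: KDE,
    starts,
    tol: float = 1e-4,
    max_iter: int = 300,
    merge_factor: float = 10.0,
):
    """Mean-shift ascent from each start point; deduplicated KDE modes.

    Ascent stops when the displacement drops below ``tol``; starts that do
    not converge within ``max_iter`` are dropped. Modes closer than
    ``merge_factor * tol`` are merged (highest-density representative kept)
    and a gradient check rejects saddle-ish leftovers.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    if isinstance(starts, SampleSet):
        starts = starts.points
    X = np.atleast_2d(np.asarray(starts, dtype=float)).copy()
    active = np.ones(X.shape[0], dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        moved = kde.mean_shift_batch(X[active])
        disp = np.linalg.norm(moved - X[active], axis=1)
        X[active] = moved
        idx = np.flatnonzero(active)
        active[idx[disp < tol]] = False
    converged = ~active
    X = X[converged]
    if X.shape[0] == 0:
        return []
    dens = kde.density_batch(X)
    order = np.argsort(-dens)
    modes, mdens = [], []
    for i in order:
        if any(np.linalg.norm(X[i] - m) < merge_factor * tol for m in modes):
            continue
        # gradient must be ~0 relative to the density scale
        g = np.linalg.norm(kde.gradient(X[i]))
        if g > 1e-2 * max(dens[i], 1e-300) / kde.h:
            continue
        modes.append(X[i].copy())
        mdens.append(dens[i])
    return modes


# ---------------------------------------------------------------------------
# ridge geometry

def _eig_sorted(Hm):
    """Eigen-decomposition with eigenvalues ascending (strong curvature first)."""
    evals, evecs = np.linalg.eigh(Hm)
    return evals, evecs  # evals[0] <= evals[1]; evecs[:, k] matches evals[k]


def ridge_residual(kde: KDE, x) -> float:
    """|v_strong . grad| / |grad|: zero on the ridge (and at modes)."""
    g = kde.gradient(x)
    ng = np.linalg.norm(g)
    if ng < 1e-300:
        return 0.0
    _, evecs = _eig_sorted(kde.hessian(x))
    return float(abs(evecs[:, 0] @ g) / ng)


def project_to_ridge(kde: KDE, x, tol: float = 1e-4, max_iter: int = 200) -> np.ndarray:
    """Subspace-constrained mean shift: project x onto the ridge set.

    Each step moves by the component of the mean-shift vector along the
    strong-curvature Hessian eigenvector, so iterates slide across the
    ridge without drifting along it. Raises :class:`ConvergenceError`
    (carrying the last iterate) if ``max_iter`` is exhausted.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    x = np.asarray(x, dtype=float).copy()
    for _ in range(max_iter):
        m = kde.mean_shift(x)
        _, evecs = _eig_sorted(kde.hessian(x))
        v = evecs[:, 0]
        step = v * (v @ (m - x))
        x = x + step
        if np.linalg.norm(step) < tol:
            return x
    raise ConvergenceError("ridge projection did not converge", last=x)


def _tangent(kde: KDE, x, prev_dir=None) -> np.ndarray:
    """Unit weak-curvature eigenvector at x, sign-aligned with prev_dir."""
    _, evecs = _eig_sorted(kde.hessian(x))
    t = evecs[:, 1]
    if prev_dir is not None and t @ prev_dir < 0:
        t = -t
    return t


def trace_ridge(
    kde: KDE,
    seed,
    step: float = 1.0,
    theta: float = 0.0,
    max_len: int = 2000,
    domain=None,
    tol: float = 1e-3,
) -> RidgeCurve:
    """Trace the ridge curve through a mode, bidirectionally.

    Predictor: advance ``step`` along the weak-curvature eigenvector.
    Corrector: subspace-constrained mean shift back onto the ridge.
    Terminates on density <= theta, on leaving ``domain``
    (rmin, rmax, cmin, cmax), on stalling, or after ``max_len`` points
    per direction.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    seed = np.asarray(seed, dtype=float)
    if kde.density(seed) <= theta:
        return RidgeCurve(np.empty((0, 2)), np.empty(0))
    t0 = _tangent(kde, seed)

    def march(direction):
        pts = []
        x = seed.copy()
        d = direction.copy()
        for _ in range(max_len):
            xp = x + step * d
            try:
                xc = project_to_ridge(kde, xp, tol=tol)
            except ConvergenceError:
                break
            dens = kde.density(xc)
            if dens <= theta:
                break
            if domain is not None:
                rmin, rmax, cmin, cmax = domain
                if not (rmin <= xc[0] <= rmax and cmin <= xc[1] <= cmax):
                    break
            adv = xc - x
            nadv = np.linalg.norm(adv)
            if nadv < 0.25 * step:       # stalled (isotropic blob, ridge end)
                break
            if adv @ d < 0:              # corrector reversed: ridge exhausted
                break
            pts.append((xc, dens))
            d = _tangent(kde, xc, prev_dir=adv / nadv)
            x = xc
        return pts

    fwd = march(t0)
    bwd = march(-t0)
    points = [p for p, _ in reversed(bwd)] + [seed] + [p for p, _ in fwd]
    dens = (
        [v for _, v in reversed(bwd)]
        + [float(kde.density(seed))]
        + [v for _, v in fwd]
    )
    return RidgeCurve(np.array(points), np.array(dens))


def segment_curves(curves, theta: float, min_len: int = 5):
    """Split curves at points with density <= theta; drop short fragments."""
    if theta < 0:
        raise ValidationError("theta must be >= 0")
    out = []
    for c in curves:
        keep = c.density > theta
        if keep.all():
            if len(c) >= min_len:
                out.append(c)
            continue
        start = None
        for i, k in enumerate(np.append(keep, False)):
            if k and start is None:
                start = i
            elif not k and start is not None:
                if i - start >= min_len:
                    out.append(RidgeCurve(c.points[start:i], c.density[start:i]))
                start = None
    return out


# ---------------------------------------------------------------------------
# spur pruning

def _branch_dir(points: np.ndarray, n: int = 5) -> np.ndarray:
    """Mean outgoing direction over the first ~n points of a branch."""
    k = min(n, points.shape[0] - 1)
    if k < 1:
        return np.zeros(2)
    v = points[1 : k + 1] - points[0]
    v = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
    m = v.mean(axis=0)
    nm = np.linalg.norm(m)
    return m / nm if nm > 1e-12 else np.zeros(2)


def _arc_len(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def prune_spurs(
    graph: BackboneGraph,
    junction_radius: float = 3.0,
    spur_max_len: float = 15.0,
    max_rounds: int = 100,
) -> BackboneGraph:
    """Enforce one main through-curve per junction.

    A junction is a curve endpoint lying within ``junction_radius`` of
    another curve. Of the incident branches (the arriving curve plus the
    two halves of the curve it hits), the pair with the best angular
    continuity (angle closest to 180 deg) is kept as the main curve;
    other branches are detached, and detached branches shorter than
    ``spur_max_len`` px are deleted (these are the spine-induced spurs).
    """
    curves = [
        {"pts": c.points.copy(), "dens": c.density.copy(), "blocked": set()}
        for c in graph.curves
    ]
    junctions = []

    def find_junction():
        for ia, ca in enumerate(curves):
            if ca["pts"].shape[0] < 2:
                continue
            for end in (0, 1):
                if end in ca["blocked"]:
                    continue
                ep = ca["pts"][0] if end == 0 else ca["pts"][-1]
                for ib, cb in enumerate(curves):
                    if ib == ia or cb["pts"].shape[0] < 2:
                        continue
                    d = np.linalg.norm(cb["pts"] - ep, axis=1)
                    k = int(d.argmin())
                    if d[k] <= junction_radius:
                        # ignore endpoint-to-endpoint grazing: that is a
                        # continuation, handled as a 2-branch junction too
                        return ia, end, ib, k
        return None

    for _ in range(max_rounds):
        hit = find_junction()
        if hit is None:
            break
        ia, end, ib, k = hit
        ca, cb = curves[ia], curves[ib]
        J = cb["pts"][k]
        junctions.append(J.copy())
        # branch A: arriving curve, oriented away from the junction
        a_pts = ca["pts"] if end == 0 else ca["pts"][::-1]
        a_dens = ca["dens"] if end == 0 else ca["dens"][::-1]
        # branches B1, B2: halves of the hit curve, oriented away from J
        b1_pts, b1_dens = cb["pts"][: k + 1][::-1], cb["dens"][: k + 1][::-1]
        b2_pts, b2_dens = cb["pts"][k:], cb["dens"][k:]
        branches = [
            ("A", a_pts, a_dens),
            ("B1", b1_pts, b1_dens),
            ("B2", b2_pts, b2_dens),
        ]
        usable = [b for b in branches if b[1].shape[0] >= 2]
        # choose the pair with outgoing directions closest to opposite
        best, best_cos = None, np.inf
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                c = _branch_dir(usable[i][1]) @ _branch_dir(usable[j][1])
                if c < best_cos:
                    best_cos, best = c, (usable[i][0], usable[j][0])
        if best is None:
            ca["blocked"].add(end)
            continue
        names = set(best)
        new_curves = []

        def keep_detached(pts, dens):
            if _arc_len(pts) >= spur_max_len and pts.shape[0] >= 2:
                # candidate side-dendrite; block its junction end
                new_curves.append(
                    {"pts": pts, "dens": dens, "blocked": {0}}
                )

        if names == {"B1", "B2"}:
            # hit curve passes through; arriving curve is the side branch
            new_curves.append({"pts": cb["pts"], "dens": cb["dens"],
                               "blocked": cb["blocked"]})
            keep_detached(a_pts, a_dens)
        else:
            other = ({"B1", "B2"} - names).pop() if "A" in names else None
            half = {"B1": (b1_pts, b1_dens), "B2": (b2_pts, b2_dens)}
            keep_name = (names - {"A"}).pop()
            kp, kd = half[keep_name]
            merged_pts = np.vstack([a_pts[::-1], kp[1:]])
            merged_dens = np.concatenate([a_dens[::-1], kd[1:]])
            blocked = set()
            if end in ca["blocked"]:
                pass  # arriving end is consumed by the merge
            if (0 if end == 0 else 1) in ca["blocked"]:
                blocked.add(0)
            new_curves.append(
                {"pts": merged_pts, "dens": merged_dens, "blocked": blocked}
            )
            op, od = half[other]
            keep_detached(op, od)
        for idx in sorted((ia, ib), reverse=True):
            curves.pop(idx)
        curves.extend(new_curves)

    pruned = [
        RidgeCurve(c["pts"], c["dens"]) for c in curves if c["pts"].shape[0] >= 2
    ]
    return BackboneGraph(curves=pruned, theta=graph.theta, junctions=junctions)


def _trim_overlap(curve: RidgeCurve, covered, radius: float, min_len: int):
    """Drop curve points within ``radius`` of already-accepted ridge points;
    return the remaining contiguous runs of length >= min_len."""
    if len(curve) == 0:
        return []
    if covered is None:
        return [curve] if len(curve) >= min_len else []
    d, _ = covered.query(curve.points)
    keep = d > radius
    runs = []
    start = None
    for i, k in enumerate(np.append(keep, False)):
        if k and start is None:
            start = i
        elif not k and start is not None:
            if i - start >= min_len:
                runs.append(RidgeCurve(curve.points[start:i], curve.density[start:i]))
            start = None
    return runs


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class BackboneConfig:
    """Tunables for backbone extraction (pixel units)."""

    bandwidth_px: float = 3.0
    ridge_step: float = 1.5
    theta_fraction: float = 0.1
    spur_max_len: float = 15.0
    junction_radius: float | None = None   # default 2 * ridge_step
    max_samples: int = 20000
    n_mode_starts: int = 150
    min_len: int = 5
    max_curve_points: int = 3000


def extract_backbone(mask: BinaryMask, config: BackboneConfig | None = None) -> BackboneGraph:
    """Full backbone extraction from a binary foreground mask.

    Samples are the foreground pixel centres (deterministically thinned to
    ``max_samples``); modes seed predictor-corrector ridge traces; traced
    curves are cut at the low-density threshold
    theta = theta_fraction * median mode density and spur-pruned.
    """
    cfg = config or BackboneConfig()
    if isinstance(mask, BinaryMask):
        m = mask.pixels
    else:
        m = np.asarray(mask).astype(bool)
    pts = np.argwhere(m).astype(float)
    if pts.shape[0] == 0:
        raise ValidationError("empty mask: nothing to extract")
    stride = int(np.ceil(pts.shape[0] / cfg.max_samples))
    samples = pts[::stride]
    kde = KDE(samples, cfg.bandwidth_px)
    start_stride = max(1, int(np.ceil(samples.shape[0] / cfg.n_mode_starts)))
    starts = samples[::start_stride]
    modes = find_modes(kde, starts, tol=1e-3 * cfg.bandwidth_px)
    if not modes:
        return BackboneGraph(curves=[], theta=0.0)
    mode_dens = kde.density_batch(np.array(modes))
    theta = cfg.theta_fraction * float(np.median(mode_dens))
    pad = 3.0 * cfg.bandwidth_px
    domain = (-pad, m.shape[0] - 1 + pad, -pad, m.shape[1] - 1 + pad)
    order = np.argsort(-mode_dens)
    curves = []
    covered = None
    for i in order:
        mode = modes[i]
        if covered is not None:
            d, _ = covered.query(mode)
            if d < 1.5 * cfg.ridge_step:
                continue
        curve = trace_ridge(
            kde, mode, step=cfg.ridge_step, theta=theta,
            max_len=cfg.max_curve_points, domain=domain,
        )
        # a trace seeded off the main ridge (e.g. on a spine) runs onto
        # curves already traced; trim the overlap, keep the novel runs
        for piece in _trim_overlap(curve, covered, cfg.ridge_step, cfg.min_len):
            curves.append(piece)
        if curves:
            covered = cKDTree(np.vstack([c.points for c in curves]))
    curves = segment_curves(curves, theta, min_len=cfg.min_len)
    jr = cfg.junction_radius if cfg.junction_radius is not None else 2.0 * cfg.ridge_step
    graph = BackboneGraph(curves=curves, theta=theta)
    return prune_spurs(graph, junction_radius=jr, spur_max_len=cfg.spur_max_len)
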