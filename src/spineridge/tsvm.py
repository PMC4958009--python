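"""Twin support vector machine (TSVM) classifiers.

A TSVM fits one hyperplane (or kernel surface) per class: each plane is
pulled close to its own class in least squares while the other class is
pushed to unit distance, softened by hinge slacks. Training therefore
solves two small convex QPs instead of one large one, and a sample is
classified by whichever plane it is nearer to.

With G = [A, e1] and H = [B, e2] (rows = samples, last column = 1), the
class-(+1) plane z1 = (w1, b1) solves

    min_z,q  1/2 ||G z||^2 + c1 e2^T q   s.t.  -(H z) + q >= e2, q >= 0,

whose Wolfe dual is the box QP  max_a e2^T a - 1/2 a^T H (G^T G)^-1 H^T a,
0 <= a <= c1, with z1 = -(G^T G + eps I)^-1 H^T a. The class-(-1) problem
is the mirror image (constraint sign flipped), giving
z2 = +(H^T H + eps I)^-1 G^T b. Kernel surfaces replace A, B by Gaussian
kernel blocks K(A, C^T), K(B, C^T) against the reference matrix C = [A; B].

Multiclass (mushroom / stubby / thin) uses one-vs-rest with nearest
own-surface distance aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._qp import solve_box_qp
from .errors import ValidationError

_EPS_REG_DEFAULT = 1e-8
# kernel duals involve (N^T N + eps I)^-1 with N^T N low-rank; a larger eps
# keeps the dual Hessian conditioned without visibly moving the surfaces
# (the classic TWSVM ridge term; holdout accuracy is flat from 1e-4 to 1e-1)
_EPS_REG_KERNEL = 1e-2


@dataclass
class TrainingSet:
    """Binary training data: A = class (+1) rows, B = class (-1) rows."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.A.size == 0 or self.B.size == 0:
            raise ValidationError("both classes must be non-empty")
        if self.A.shape[1] != self.B.shape[1]:
            raise ValidationError("A and B must share a feature dimension")

    @property
    def e1(self) -> np.ndarray:
        return np.ones(self.A.shape[0])

    @property
    def e2(self) -> np.ndarray:
        return np.ones(self.B.shape[0])


@dataclass
class TSVMModel:
    """Pair of nonparallel planes/surfaces with their hyperparameters.

    ``mode`` is 'linear' or 'kernel'. In linear mode ``z1``/``z2`` are
    (d+1)-vectors [w, b]; in kernel mode they are (N_ref+1)-vectors [u, b]
    with reference matrix ``C`` and Gaussian width ``gamma_k``
    (``kernel='linear'`` uses the plain inner product instead).
    """

    mode: str
    z1: np.ndarray
    z2: np.ndarray
    c1: float
    c2: float
    C: np.ndarray | None = None
    gamma_k: float | None = None
    kernel: str = "rbf"
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    dual1: np.ndarray | None = field(default=None, repr=False)
    dual2: np.ndarray | None = field(default=None, repr=False)
    dual_objectives: tuple | None = None

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_scale

    # --- geometry -------------------------------------------------
    def _plane_norms(self):
        if self.mode == "linear":
            n1 = float(np.linalg.norm(self.z1[:-1]))
            n2 = float(np.linalg.norm(self.z2[:-1]))
        else:
            K = _kernel_matrix(self.C, self.C, self.gamma_k, self.kernel)
            n1 = float(np.sqrt(max(self.z1[:-1] @ K @ self.z1[:-1], 0.0)))
            n2 = float(np.sqrt(max(self.z2[:-1] @ K @ self.z2[:-1], 0.0)))
        return max(n1, 1e-300), max(n2, 1e-300)

    def surface_values(self, X: np.ndarray):
        """Signed surface responses (f1, f2) for sample rows X."""
        X = self._standardize(np.atleast_2d(np.asarray(X, dtype=float)))
        if self.mode == "linear":
            F = X
        else:
            F = _kernel_matrix(X, self.C, self.gamma_k, self.kernel)
        f1 = F @ self.z1[:-1] + self.z1[-1]
        f2 = F @ self.z2[:-1] + self.z2[-1]
        return f1, f2

    def distances(self, X: np.ndarray):
        """Normalized plane distances (d1, d2) for sample rows X."""
        f1, f2 = self.surface_values(X)
        n1, n2 = self._plane_norms()
        return np.abs(f1) / n1, np.abs(f2) / n2

    # --- serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "z1": self.z1.tolist(),
            "z2": self.z2.tolist(),
            "c1": self.c1,
            "c2": self.c2,
            "kernel": self.kernel,
            "gamma_k": self.gamma_k,
        }
        if self.C is not None:
            d["C"] = self.C.tolist()
        if self.feature_mean is not None:
            d["feature_mean"] = self.feature_mean.tolist()
            d["feature_scale"] = self.feature_scale.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TSVMModel":
        return cls(
            mode=d["mode"],
            z1=np.asarray(d["z1"], dtype=float),
            z2=np.asarray(d["z2"], dtype=float),
            c1=d["c1"],
            c2=d["c2"],
            C=np.asarray(d["C"], dtype=float) if "C" in d else None,
            gamma_k=d.get("gamma_k"),
            kernel=d.get("kernel", "rbf"),
            feature_mean=(np.asarray(d["feature_mean"], dtype=float)
                          if "feature_mean" in d else None),
            feature_scale=(np.asarray(d["feature_scale"], dtype=float)
                           if "feature_scale" in d else None),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TSVMModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _kernel_matrix(X, C, gamma_k, kernel="rbf"):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if kernel == "linear":
        return X @ C.T
    sq = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(C * C, axis=1)[None, :]
        - 2.0 * X @ C.T
    )
    return np.exp(-gamma_k * np.maximum(sq, 0.0))


def _fit_scaler(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return mean, scale


def median_heuristic_gamma(X: np.ndarray) -> float:
    """Gaussian width 1/(2 m^2) with m = median pairwise distance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n > 400:  # deterministic thinning for large sets
        X = X[:: int(np.ceil(n / 400))]
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(X * X, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    d2 = d2[np.triu_indices_from(d2, k=1)]
    d2 = d2[d2 > 1e-20]
    if d2.size == 0:
        return 1.0
    m2 = float(np.median(d2))
    return 1.0 / (2.0 * m2)


def _solve_pair(L: np.ndarray, N: np.ndarray, c1: float, c2: float, eps_reg: float):
    """Solve both TSVM duals for design blocks L (class +1) and N (class -1).

    Returns (z1, z2, a, g, obj1, obj2): z1 = -(L^T L + eps)^-1 N^T a with
    0 <= a <= c1, z2 = +(N^T N + eps)^-1 L^T g with 0 <= g <= c2.
    """
    d = L.shape[1]
    S1 = L.T @ L + eps_reg * np.eye(d)
    S2 = N.T @ N + eps_reg * np.eye(d)
    try:
        S1_inv_Nt = np.linalg.solve(S1, N.T)
        S2_inv_Lt = np.linalg.solve(S2, L.T)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular normal matrix; increase eps_reg above 0"
        ) from exc
    Q1 = N @ S1_inv_Nt
    Q2 = L @ S2_inv_Lt
    Q1 = 0.5 * (Q1 + Q1.T)
    Q2 = 0.5 * (Q2 + Q2.T)
    a = solve_box_qp(Q1, c1)
    g = solve_box_qp(Q2, c2)
    z1 = -S1_inv_Nt @ a
    z2 = S2_inv_Lt @ g
    obj1 = float(a.sum() - 0.5 * a @ Q1 @ a)
    obj2 = float(g.sum() - 0.5 * g @ Q2 @ g)
    return z1, z2, a, g, obj1, obj2


def train_linear(
    ts: TrainingSet,
    c1: float = 1.0,
    c2: float = 1.0,
    eps_reg: float = _EPS_REG_DEFAULT,
    standardize: bool = False,
) -> TSVMModel:
    """Fit the two nonparallel planes by solving the Wolfe duals of the
    twin least-squares/hinge problems as box-constrained QPs."""
    if c1 <= 0 or c2 <= 0:
        raise ValidationError("c1 and c2 must be positive")
    allpts = np.vstack([ts.A, ts.B])
    if np.allclose(allpts, allpts[0], atol=1e-12):
        raise ValidationError("degenerate training set: all points identical")
    mean = scale = None
    A, B = ts.A, ts.B
    if standardize:
        mean, scale = _fit_scaler(allpts)
        A = (A - mean) / scale
        B = (B - mean) / scale
    G = np.hstack([A, ts.e1[:, None]])
    H = np.hstack([B, ts.e2[:, None]])
    z1, z2, a, g, o1, o2 = _solve_pair(G, H, c1, c2, eps_reg)
    return TSVMModel(
        mode="linear", z1=z1, z2=z2, c1=c1, c2=c2,
        feature_mean=mean, feature_scale=scale,
        dual1=a, dual2=g, dual_objectives=(o1, o2),
    )


def train_kernel(
    ts: TrainingSet,
    c1: float = 1.0,
    c2: float = 1.0,
    gamma_k: float | None = None,
    eps_reg: float = _EPS_REG_KERNEL,
    kernel: str = "rbf",
    standardize: bool = False,
    gamma_scale: float = 1.0,
) -> TSVMModel:
    """Fit the two kernel surfaces K(x, C^T) u + b = 0 (C = [A; B])."""
    if c1 <= 0 or c2 <= 0:
        raise ValidationError("c1 and c2 must be positive")
    A, B = ts.A, ts.B
    mean = scale = None
    if standardize:
        mean, scale = _fit_scaler(np.vstack([A, B]))
        A = (A - mean) / scale
        B = (B - mean) / scale
        ts = TrainingSet(A=A, B=B)
    C = np.vstack([ts.A, ts.B])
    if kernel == "rbf":
        if gamma_k is None:
            gamma_k = gamma_scale * median_heuristic_gamma(C)
        if gamma_k <= 0:
            raise ValidationError("gamma_k must be positive")
        # gamma_k -> 0 collapses the kernel matrix to all-ones
        KCC = _kernel_matrix(C, C, gamma_k, "rbf")
        if KCC.min() > 0.999:
            raise ValidationError(
                "gamma_k too small: kernel matrix is numerically constant"
            )
    L = np.hstack([_kernel_matrix(ts.A, C, gamma_k, kernel), ts.e1[:, None]])
    N = np.hstack([_kernel_matrix(ts.B, C, gamma_k, kernel), ts.e2[:, None]])
    if eps_reg == 0:
        eps_reg = 0.0  # honoured, but singular N^T N will raise below
    z1, z2, a, g, o1, o2 = _solve_pair(L, N, c1, c2, eps_reg)
    return TSVMModel(
        mode="kernel", z1=z1, z2=z2, c1=c1, c2=c2, C=C,
        gamma_k=gamma_k, kernel=kernel,
        feature_mean=mean, feature_scale=scale,
        dual1=a, dual2=g, dual_objectives=(o1, o2),
    )


def predict(model: TSVMModel, x: np.ndarray):
    """Classify one sample by the nearer plane.

    Returns (label, (d1, d2)) with label +1/-1; ties (|d1 - d2| < 1e-12)
    break to +1 for determinism.
    """
    if model is None or model.z1 is None:
        raise ValidationError("model is not trained")
    d1, d2 = model.distances(np.atleast_2d(x))
    d1, d2 = float(d1[0]), float(d2[0])
    label = 1 if d1 <= d2 + 1e-12 else -1
    return label, (d1, d2)


def predict_batch(model: TSVMModel, X: np.ndarray) -> np.ndarray:
    """Vectorized nearest-plane labels (+1/-1) for sample rows X."""
    d1, d2 = model.distances(X)
    return np.where(d1 <= d2 + 1e-12, 1, -1)


@dataclass
class MulticlassModel:
    """Multiclass wrapper over binary TSVMs.

    ``strategy`` is 'ovo' (one-vs-one, majority vote with a distance-ratio
    tie-break; model keys "a|b") or 'ovr' (one-vs-rest, nearest own
    surface by scale-invariant distance ratio; model keys are class names).
    """

    classes: list
    models: dict
    strategy: str = "ovo"

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "strategy": self.strategy,
            "models": {k: m.to_dict() for k, m in self.models.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MulticlassModel":
        return cls(
            classes=list(d["classes"]),
            strategy=d.get("strategy", "ovo"),
            models={k: TSVMModel.from_dict(v) for k, v in d["models"].items()},
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "MulticlassModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_multiclass(
    features: np.ndarray,
    labels,
    c1: float = 1.0,
    c2: float = 1.0,
    gamma_k: float | None = None,
    mode: str = "kernel",
    classes=None,
    standardize: bool = False,
    strategy: str = "ovo",
    gamma_scale: float = 2.0,
) -> MulticlassModel:
    """Train binary TSVMs for the named classes (>= 2 examples each).

    The default strategy is one-vs-one: one TSVM per class pair, combined
    by majority vote (pairwise distances between two dedicated surfaces
    are better calibrated than one-vs-rest distances, whose scales are
    not commensurable across models).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    for cls_name in classes:
        if (labels == cls_name).sum() < 2:
            raise ValidationError(f"class {cls_name!r} needs >= 2 examples")

    def fit(A, B):
        ts = TrainingSet(A=A, B=B)
        if mode == "kernel":
            return train_kernel(ts, c1=c1, c2=c2, gamma_k=gamma_k,
                                standardize=standardize,
                                gamma_scale=gamma_scale)
        return train_linear(ts, c1=c1, c2=c2, standardize=standardize)

    models = {}
    if strategy == "ovo":
        import itertools

        for a, b in itertools.combinations(classes, 2):
            models[f"{a}|{b}"] = fit(X[labels == a], X[labels == b])
    else:
        for cls_name in classes:
            models[cls_name] = fit(X[labels == cls_name],
                                   X[labels != cls_name])
    return MulticlassModel(classes=list(classes), models=models,
                           strategy=strategy)


def predict_multiclass(mc: MulticlassModel, X: np.ndarray):
    """Label each sample row by the trained multiclass model.

    One-vs-one: majority vote over pairwise models, ties broken by the
    summed pairwise distance ratios. One-vs-rest: smallest ratio of the
    own-surface to the rest-surface distance (scale-invariant).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = len(mc.classes)
    if mc.strategy == "ovo":
        votes = np.zeros((X.shape[0], k))
        soft = np.zeros((X.shape[0], k))
        for key, m in mc.models.items():
            a, b = key.split("|")
            ia, ib = mc.classes.index(a), mc.classes.index(b)
            d1, d2 = m.distances(X)
            w = d1 <= d2
            votes[:, ia] += w
            votes[:, ib] += ~w
            tot = np.maximum(d1 + d2, 1e-300)
            soft[:, ia] += d1 / tot
            soft[:, ib] += d2 / tot
        score = votes - 1e-3 * soft
        idx = score.argmax(axis=1)
    else:
        scores = []
        for c in mc.classes:
            d_own, d_rest = mc.models[c].distances(X)
            scores.append(d_own / np.maximum(d_rest, 1e-300))
        idx = np.column_stack(scores).argmin(axis=1)
    return [mc.classes[i] for i in idx]
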