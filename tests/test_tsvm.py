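"""Twin-SVM training (linear + kernel), prediction and the QP dual solver.

The independent oracle throughout is scipy.optimize L-BFGS-B run on the
same box-constrained dual; the in-package solver is spectral projected
gradient + coordinate ascent, so agreement is a genuine cross-check.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from spineridge._qp import kkt_residual, qp_objective, solve_box_qp
from spineridge.errors import ValidationError
from spineridge.tsvm import (
    MulticlassModel,
    TrainingSet,
    TSVMModel,
    predict,
    predict_batch,
    predict_multiclass,
    train_kernel,
    train_linear,
    train_multiclass,
)


def _oracle_box_qp(Q, ub):
    # L-BFGS-B with restarts: a single run can stall on flat regions of
    # the box-constrained dual, a restart resets its Hessian memory
    n = Q.shape[0]
    x = np.zeros(n)
    best = None
    for _ in range(6):
        res = minimize(
            lambda v: -(v.sum() - 0.5 * v @ Q @ v),
            x,
            jac=lambda v: -(1.0 - Q @ v),
            bounds=[(0.0, ub)] * n,
            method="L-BFGS-B",
            options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 10000},
        )
        x = res.x
        if best is not None and -res.fun <= best + 1e-15:
            break
        best = -res.fun
    return x, best


class TestBoxQP:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_lbfgsb_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 30))
        M = r.normal(size=(n, n))
        Q = M @ M.T / n + 1e-6 * np.eye(n)
        ub = float(r.uniform(0.5, 3.0))
        g = solve_box_qp(Q, ub, tol=1e-10)
        _, ref_obj = _oracle_box_qp(Q, ub)
        assert abs(qp_objective(Q, g) - ref_obj) < 1e-6
        assert kkt_residual(Q, g, ub) < 1e-6


class TestTrainLinear:
    def test_separated_horizontal_classes(self, rng):
        A = np.column_stack([rng.uniform(-5, 5, 30), np.zeros(30)])
        B = np.column_stack([rng.uniform(-5, 5, 30), np.full(30, 10.0)])
        m = train_linear(TrainingSet(A, B), c1=0.1, c2=0.1)
        # plane 1 fits A (x2 = 0): least-squares residual tiny
        f1, _ = m.surface_values(A)
        assert np.abs(f1).max() < 1e-3
        _, f2 = m.surface_values(B)
        assert np.abs(f2).max() < 1e-3
        assert (predict_batch(m, A) == 1).all()
        assert (predict_batch(m, B) == -1).all()

    def test_cross_planes_data(self, rng):
        t = rng.uniform(-5, 5, 40)
        A = np.column_stack([t, t])          # on y = x
        s = rng.uniform(-5, 5, 40)
        B = np.column_stack([s, -s])         # on y = -x
        # cross data puts each class on both sides of the other's plane,
        # so a small hinge penalty lets the least-squares term pin each
        # plane onto its line
        m = train_linear(TrainingSet(A, B), c1=1e-3, c2=1e-3, eps_reg=1e-4)
        w1 = m.z1[:-1] / np.linalg.norm(m.z1[:-1])
        w2 = m.z2[:-1] / np.linalg.norm(m.z2[:-1])
        # plane normals align with (1,-1) and (1,1) within 2 degrees
        assert abs(abs(w1 @ np.array([1, -1]) / np.sqrt(2)) - 1) < np.sin(np.radians(2))
        assert abs(abs(w2 @ np.array([1, 1]) / np.sqrt(2)) - 1) < np.sin(np.radians(2))
        labels = np.concatenate([predict_batch(m, A), predict_batch(m, B)])
        truth = np.concatenate([np.ones(40), -np.ones(40)])
        assert (labels == truth).mean() == 1.0

    def test_duals_match_reference(self, rng):
        A = rng.normal(size=(12, 3)) + 1.0
        B = rng.normal(size=(15, 3)) - 1.0
        ts = TrainingSet(A, B)
        m = train_linear(ts, c1=0.7, c2=1.3)
        G = np.hstack([A, np.ones((12, 1))])
        H = np.hstack([B, np.ones((15, 1))])
        eps = 1e-8
        S1 = G.T @ G + eps * np.eye(4)
        Q1 = H @ np.linalg.solve(S1, H.T)
        Q1 = 0.5 * (Q1 + Q1.T)
        a_ref, obj_ref = _oracle_box_qp(Q1, 0.7)
        assert abs(m.dual_objectives[0] - obj_ref) < 1e-6
        z_ref = -np.linalg.solve(S1, H.T @ a_ref)
        np.testing.assert_allclose(m.z1, z_ref, atol=1e-4)

    def test_swap_symmetry(self, rng):
        A = rng.normal(size=(10, 2)) + 2
        B = rng.normal(size=(10, 2)) - 2
        m1 = train_linear(TrainingSet(A, B), c1=0.5, c2=2.0)
        m2 = train_linear(TrainingSet(B, A), c1=2.0, c2=0.5)
        # swapping classes and penalties swaps the planes (up to sign)
        r1 = m1.z1 / np.linalg.norm(m1.z1)
        r2 = m2.z2 / np.linalg.norm(m2.z2)
        assert min(np.abs(r1 - r2).max(), np.abs(r1 + r2).max()) < 1e-4

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            train_linear(TrainingSet(np.ones((5, 2)), np.ones((5, 2))))


class TestTrainKernel:
    def test_concentric_circles(self, rng):
        a1 = rng.uniform(0, 2 * np.pi, 50)
        a2 = rng.uniform(0, 2 * np.pi, 50)
        A = np.column_stack([np.cos(a1), np.sin(a1)])
        B = 3.0 * np.column_stack([np.cos(a2), np.sin(a2)])
        m = train_kernel(TrainingSet(A, B), gamma_k=1.0)
        X = np.vstack([A, B])
        y = np.concatenate([np.ones(50), -np.ones(50)])
        assert (predict_batch(m, X) == y).mean() == 1.0

    def test_tiny_gamma_degenerate(self, rng):
        A = rng.normal(size=(10, 2))
        B = rng.normal(size=(10, 2)) + 5
        with pytest.raises(ValidationError):
            train_kernel(TrainingSet(A, B), gamma_k=1e-12)

    def test_linear_kernel_matches_linear_planes(self, rng):
        A = rng.normal(size=(15, 3)) + np.array([2.0, 0, 0])
        B = rng.normal(size=(15, 3)) - np.array([2.0, 0, 0])
        ml = train_linear(TrainingSet(A, B), eps_reg=1e-10)
        mk = train_kernel(TrainingSet(A, B), kernel="linear", eps_reg=1e-10)
        # kernel surface K(x,C)u + b = x.(C^T u) + b: same plane geometry
        w_eff = mk.C.T @ mk.z1[:-1]
        z_k = np.append(w_eff, mk.z1[-1])
        z_l = ml.z1
        z_k = z_k / np.linalg.norm(z_k)
        z_l = z_l / np.linalg.norm(z_l)
        assert min(np.abs(z_k - z_l).max(), np.abs(z_k + z_l).max()) < 1e-4


class TestPredict:
    def _manual_model(self):
        # plane 1: x2 = 0; plane 2: x2 = 10
        return TSVMModel(mode="linear", z1=np.array([0.0, 1.0, 0.0]),
                         z2=np.array([0.0, 1.0, -10.0]), c1=1, c2=1)

    def test_on_plane_zero_distance(self):
        lab, (d1, d2) = predict(self._manual_model(), [3.0, 0.0])
        assert lab == 1 and d1 == pytest.approx(0.0)

    def test_distances_example(self):
        lab, (d1, d2) = predict(self._manual_model(), [0.0, 2.0])
        assert lab == 1
        assert d1 == pytest.approx(2.0) and d2 == pytest.approx(8.0)

    def test_tie_breaks_positive(self):
        lab, _ = predict(self._manual_model(), [0.0, 5.0])
        assert lab == 1

    def test_rescaling_invariance(self):
        m = self._manual_model()
        m2 = TSVMModel(mode="linear", z1=7.3 * m.z1, z2=0.2 * m.z2, c1=1, c2=1)
        for x in ([0.0, 2.0], [1.0, 9.0], [0.0, 5.0]):
            assert predict(m, x)[0] == predict(m2, x)[0]

    def test_untrained_rejected(self):
        with pytest.raises(ValidationError):
            predict(None, [0.0, 0.0])


class TestMulticlass:
    def test_three_gaussian_clusters(self, rng):
        centers = {"a": (0, 0), "b": (8, 0), "c": (0, 8)}
        X, y = [], []
        for name, c in centers.items():
            X.append(rng.normal(0, 0.6, size=(40, 2)) + c)
            y += [name] * 40
        X = np.vstack(X)
        y = np.array(y)
        tr = np.tile(np.arange(40) < 30, 3)
        mc = train_multiclass(X[tr], y[tr], classes=["a", "b", "c"])
        pred = np.array(predict_multiclass(mc, X[~tr]))
        assert (pred == y[~tr]).mean() >= 0.95

    def test_missing_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = ["a"] * 9 + ["b"]
        with pytest.raises(ValidationError):
            train_multiclass(X, y, classes=["a", "b"])

    def test_serialization_roundtrip(self, rng, tmp_path):
        X = np.vstack([rng.normal(size=(20, 3)), rng.normal(size=(20, 3)) + 4])
        y = np.array(["p"] * 20 + ["q"] * 20)
        mc = train_multiclass(X, y, classes=["p", "q"])
        p = tmp_path / "mc.json"
        mc.save(p)
        mc2 = MulticlassModel.load(p)
        assert predict_multiclass(mc, X) == predict_multiclass(mc2, X)
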