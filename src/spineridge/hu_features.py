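"""Image moments and the seven Hu invariants used as spine shape features.

Raw moments M_pq = sum_x sum_y x^p y^q I(x,y) (x = column, y = row),
central moments mu_pq about the centroid, normalized central moments
eta_pq = mu_pq / mu_00^(1+(p+q)/2), and the seven Hu polynomial
combinations, which are invariant to translation, scale and rotation.
By default moments are computed on the binary region mask; an
intensity-weighted variant is available via the ``weighted`` flag on
:func:`feature_vector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class MomentSet:
    """Raw, central and normalized central moments up to order 3."""

    raw: np.ndarray            # (4,4), raw[p, q] = M_pq
    centroid: tuple            # (x_bar, y_bar)
    central: np.ndarray = field(default=None)   # mu[p, q]
    eta: np.ndarray = field(default=None)       # eta[p, q]


@dataclass
class HuVector:
    """The seven Hu moment invariants H1..H7."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (7,):
            raise ValidationError("HuVector needs exactly 7 components")


def raw_moments(image: np.ndarray) -> MomentSet:
    """Raw moments M_pq for p, q in 0..3 of a 2-D intensity array."""
    I = np.asarray(image, dtype=float)
    if I.ndim != 2:
        raise ValidationError("moment input must be a 2-D array")
    total = I.sum()
    if total <= 0:
        raise ValidationError("moments undefined for an all-zero image")
    ys = np.arange(I.shape[0], dtype=float)   # y = row
    xs = np.arange(I.shape[1], dtype=float)   # x = col
    xp = np.vander(xs, 4, increasing=True)    # (W, 4) columns x^0..x^3
    yp = np.vander(ys, 4, increasing=True)    # (H, 4)
    # M[p, q] = sum_{r,c} c^p r^q I[r, c]
    M = np.einsum("rc,cp,rq->pq", I, xp, yp)
    centroid = (M[1, 0] / M[0, 0], M[0, 1] / M[0, 0])
    return MomentSet(raw=M, centroid=centroid)


def central_moments(ms: MomentSet, image: np.ndarray | None = None) -> MomentSet:
    """Central moments mu_pq about the centroid.

    Computed from the raw moments by the binomial expansion; if ``image``
    is given, direct summation is used instead (the two agree to 1e-9,
    asserted by the test suite).
    """
    if ms.raw is None:
        raise ValidationError("raw moments required first")
    xb, yb = ms.centroid
    mu = np.zeros((4, 4))
    if image is not None:
        I = np.asarray(image, dtype=float)
        ys = np.arange(I.shape[0], dtype=float) - yb
        xs = np.arange(I.shape[1], dtype=float) - xb
        xp = np.vander(xs, 4, increasing=True)
        yp = np.vander(ys, 4, increasing=True)
        mu = np.einsum("rc,cp,rq->pq", I, xp, yp)
    else:
        from math import comb

        M = ms.raw
        for p in range(4):
            for q in range(4):
                s = 0.0
                for i in range(p + 1):
                    for j in range(q + 1):
                        s += (
                            comb(p, i) * comb(q, j)
                            * (-xb) ** (p - i) * (-yb) ** (q - j)
                            * M[i, j]
                        )
                mu[p, q] = s
    ms.central = mu
    return ms


def normalized_central(ms: MomentSet) -> MomentSet:
    """eta_pq = mu_pq / mu_00^(1 + (p+q)/2): scale + translation invariant."""
    if ms.central is None:
        raise ValidationError("central moments required first")
    mu00 = ms.central[0, 0]
    if mu00 <= 0:
        raise ValidationError("mu_00 must be positive")
    eta = np.zeros((4, 4))
    for p in range(4):
        for q in range(4):
            eta[p, q] = ms.central[p, q] / mu00 ** (1.0 + (p + q) / 2.0)
    ms.eta = eta
    return ms


def hu_invariants(ms: MomentSet) -> HuVector:
    """The seven Hu polynomial combinations of the normalized moments."""
    if ms.eta is None:
        raise ValidationError("normalized central moments required first")
    n = ms.eta
    n20, n02, n11 = n[2, 0], n[0, 2], n[1, 1]
    n30, n03, n21, n12 = n[3, 0], n[0, 3], n[2, 1], n[1, 2]
    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (
        3 * (n30 + n12) ** 2 - (n21 + n03) ** 2
    )
    h6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    h7 = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (
        3 * (n30 + n12) ** 2 - (n21 + n03) ** 2
    )
    return HuVector(np.array([h1, h2, h3, h4, h5, h6, h7]))


def moments_of(image: np.ndarray) -> MomentSet:
    """Full moment set (raw, central, normalized) of an intensity array."""
    ms = raw_moments(image)
    ms = central_moments(ms, image=image)
    return normalized_central(ms)


def hu_of(image: np.ndarray) -> HuVector:
    """Hu invariants of an intensity (or binary) 2-D array."""
    return hu_invariants(moments_of(image))


_LOG_FLOOR = 1e-30


def feature_vector(region, weighted: bool = False) -> np.ndarray:
    """Log-magnitude-scaled Hu features of a spine region.

    f_i = sign(H_i) * log10(|H_i| + 1e-30); the log compresses the
    ~10-order dynamic range of H5..H7 so margin classifiers see comparable
    scales. ``region`` may be a 2-D array or anything with a
    ``to_image(weighted=...)`` method (e.g. a SpineRegion).
    """
    if hasattr(region, "to_image"):
        image = region.to_image(weighted=weighted)
    else:
        image = np.asarray(region, dtype=float)
        if not weighted:
            image = (image > 0).astype(float)
    hu = hu_of(image).values
    sign = np.where(hu < 0, -1.0, 1.0)   # sign(0) -> +1 so zero maps to -30
    return sign * np.log10(np.abs(hu) + _LOG_FLOOR)
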