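"""Shared fixtures: deterministic shapes, sample sets and tube images."""

import numpy as np
import pytest

from spineridge.density_ridge import KDE


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def line_kde():
    """KDE supported on the horizontal line row=50, cols 0..100, with a
    5-row-thick sample band (an idealized tube)."""
    ys = np.linspace(0.0, 100.0, 401)
    rows = []
    for dr in (-2.0, -1.0, 0.0, 1.0, 2.0):
        rows.append(np.stack([np.full_like(ys, 50.0 + dr), ys], axis=1))
    samples = np.concatenate(rows)
    return KDE(samples, 3.0)


def asymmetric_blob(seed, scale=1.5):
    """Three-lobe binary blob with strong third-order asymmetry, large
    enough that all seven Hu invariants are numerically stable."""
    from skimage.draw import disk as skdisk

    r = np.random.default_rng(seed)
    n = int(160 * scale)
    canvas = np.zeros((n, n))
    c0 = np.array([n / 2.0, n / 2.0])
    rr, cc = skdisk(c0, 20 * scale, shape=canvas.shape)
    canvas[rr, cc] = 1
    a1 = r.uniform(0, 2 * np.pi)
    a2 = a1 + r.uniform(1.5, 2.5)
    c1 = c0 + 24 * scale * np.array([np.cos(a1), np.sin(a1)])
    c2 = c0 + 27 * scale * np.array([np.cos(a2), np.sin(a2)])
    rr, cc = skdisk(c1, r.uniform(11, 14) * scale, shape=canvas.shape)
    canvas[rr, cc] = 1
    rr, cc = skdisk(c2, r.uniform(7, 9) * scale, shape=canvas.shape)
    canvas[rr, cc] = 1
    return canvas > 0
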