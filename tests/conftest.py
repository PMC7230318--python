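import math

import numpy as np
import pytest
from scipy import ndimage

import octaquant as oq


def thick_curve(points: np.ndarray, shape: tuple[int, int], width: int = 3) -> np.ndarray:
    """Rasterize a continuous curve as a width-px stroke (test helper)."""
    canvas = np.zeros(shape, dtype=bool)
    ij = np.round(points).astype(int)
    ok = (
        (ij[:, 0] >= 0) & (ij[:, 0] < shape[0]) & (ij[:, 1] >= 0) & (ij[:, 1] < shape[1])
    )
    canvas[ij[ok, 0], ij[ok, 1]] = True
    r = width // 2
    if r > 0:
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        canvas = ndimage.binary_dilation(canvas, structure=(yy**2 + xx**2) <= r**2)
    return canvas


@pytest.fixture
def semicircle_mask():
    """Thick semicircular arc, radius 100 px, stroke width 3."""
    th = np.linspace(0, math.pi, 4000)
    pts = np.column_stack([150 - 100 * np.sin(th), 120 + 100 * np.cos(th)])
    return thick_curve(pts, (170, 250), width=3)


@pytest.fixture
def sine_curve():
    """One period of y = 10 sin(2*pi*x/100) drawn 3 px wide, plus its
    quadrature arc length oracle."""
    x = np.linspace(0.0, 100.0, 4000)
    y = 10 * np.sin(2 * math.pi * x / 100)
    pts = np.column_stack([40 + y, 10 + x])
    dy = 2 * math.pi * 10 / 100 * np.cos(2 * math.pi * x / 100)
    arc = float(np.trapezoid(np.sqrt(1 + dy**2), x))
    return thick_curve(pts, (80, 130), width=3), arc / 100.0


@pytest.fixture(scope="session")
def default_cohort():
    return oq.generate_cohort(oq.default_cohort_params(seed=42))


def straight_branch(n: int = 30) -> oq.Branch:
    path = np.array([(5, 5 + k) for k in range(n)])
    return oq.Branch(path=path)
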