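import math

import numpy as np
import pytest

from penseg.ellipse import Ellipse


def brute_force_mask(e: Ellipse, image_size) -> np.ndarray:
    """Independent per-pixel oracle for ellipse rasterization."""
    h, w = image_size
    out = np.zeros((h, w), dtype=bool)
    r = math.radians(e.phi)
    c, s = math.cos(r), math.sin(r)
    for row in range(h):
        for col in range(w):
            dx, dy = col - e.cx, row - e.cy
            xp = dx * c + dy * s
            yp = -dx * s + dy * c
            out[row, col] = (xp / e.a) ** 2 + (yp / e.b) ** 2 <= 1.0
    return out


def random_ellipse(rng, frame=96, a_range=(6.0, 30.0), oriented=False) -> Ellipse:
    """Random ellipse fully inside a square frame (the fit-recovery family)."""
    a = rng.uniform(*a_range)
    b = rng.uniform(3.0, a)
    return Ellipse(
        cx=rng.uniform(a + 2, frame - 3 - a),
        cy=rng.uniform(a + 2, frame - 3 - a),
        a=a,
        b=max(b, 3.0),
        phi=rng.uniform(0, 360 if oriented else 180),
        oriented=oriented,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
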