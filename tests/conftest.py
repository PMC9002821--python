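"""Shared fixtures and deterministic test settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seedshape import make_model, rasterize_model

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    """Digital disk: pixel centers within ``radius`` of the center."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (radius + pad)
    return yy**2 + xx**2 <= radius**2


def square_mask(side: int, pad: int = 4) -> np.ndarray:
    m = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def ellipse_mask(a: int, b: int, pad: int = 4) -> np.ndarray:
    """Digital ellipse with semi-axes a (columns) and b (rows)."""
    yy, xx = np.mgrid[: 2 * (b + pad) + 1, : 2 * (a + pad) + 1]
    yy = yy - (b + pad)
    xx = xx - (a + pad)
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def lm1():
    return make_model("LM1")


@pytest.fixture(scope="session")
def lm1_raster(lm1):
    return rasterize_model(lm1, height_px=400)
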