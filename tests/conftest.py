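import numpy as np
import pytest

import spheroquant as sq


@pytest.fixture
def disk_mask():
    """Rasterized disk mask of radius 100 px (pixel-center rule)."""
    r = 100
    n = 2 * r + 9
    yy, xx = np.mgrid[:n, :n]
    return ((yy - n // 2) ** 2 + (xx - n // 2) ** 2) <= r * r, r


@pytest.fixture
def front_phantom():
    """250 µm spheroid with a nanocarrier front at f_pen = 0.6."""
    return sq.SpheroidPhantom(
        radius=250.0,
        pixel_size=4.0,
        marker_profiles={"nanocarrier": sq.penetration_front(0.6)},
    )


@pytest.fixture
def uniform_phantom():
    return sq.SpheroidPhantom(
        radius=250.0, pixel_size=4.0, marker_profiles={"marker": sq.uniform()}
    )


def make_disk_image(radius_px: int, shape=None, fg=0.25, bg=0.85, noise=0.0, seed=0):
    """Label-free-style dark disk on bright background."""
    n = shape or 2 * radius_px + 41
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    img = np.where((yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2, fg, bg).astype(float)
    if noise > 0:
        img += np.random.default_rng(seed).normal(0, noise, img.shape)
    return img
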