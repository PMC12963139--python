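import math

import numpy as np
import pytest

import mirrortrace as mt
from mirrortrace.simulate import (PatternSpec, default_band, generate_drawing,
                                  generate_star_image)


@pytest.fixture(scope="session")
def band512():
    return default_band(512)


@pytest.fixture(scope="session")
def band1024():
    return default_band(1024)


@pytest.fixture(scope="session")
def star512(band512):
    return generate_star_image(band512, (512, 512))


@pytest.fixture(scope="session")
def ideal_drawing(band512):
    img, g = generate_drawing(PatternSpec(pattern="ideal", seed=1),
                              band512, (512, 512))
    return img, g


def make_bump_image(band, star, centers_deg, sign, amp=1.5, dims=(512, 512),
                    theta=5, half_window_deg=15.0):
    """Trace on the ideal midline with smooth radial bumps crossing a contour."""
    from mirrortrace.simulate import _stamp
    from mirrortrace.star import polar_to_pixel

    phi = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
    g = np.zeros_like(phi)
    w = math.radians(half_window_deg)
    for c in centers_deg:
        d = np.abs((phi - math.radians(c) + np.pi) % (2 * np.pi) - np.pi)
        inside = d < w
        g[inside] = np.maximum(g[inside],
                               amp * 0.5 * (1 + np.cos(np.pi * d[inside] / w)))
    r = mt.ideal_radius(phi, band) + sign * g * mt.band_width(phi, band)
    row, col = polar_to_pixel(r, phi, band.center)
    pm = _stamp(np.stack([row, col], axis=1), theta, dims)
    return mt.HarmonizedImage(path_mask=pm, band_mask=star.band_mask,
                              border_mask=star.border_mask)
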