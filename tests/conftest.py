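import math

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Polygon

from jzmp.lesion import GATracing
from jzmp.mp_exam import UnitConventions

PX_UM = UnitConventions().um_per_faf_px  # 11.25 um per FAF pixel


def circle_polygon(center_px, radius_px, n=4096):
    """Near-exact circle polygon (vertex radius = radius_px)."""
    phi = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Polygon(
        np.column_stack(
            [center_px[0] + radius_px * np.cos(phi), center_px[1] + radius_px * np.sin(phi)]
        )
    )


def circle_of_area_mm2(center_px, area_mm2, pixel_scale_um=PX_UM, n=1024):
    """Circle component rescaled so its polygon area is exactly area_mm2."""
    r_px = math.sqrt(area_mm2 / math.pi) * 1000.0 / pixel_scale_um
    poly = circle_polygon(center_px, r_px, n)
    target_px2 = area_mm2 * (1000.0 / pixel_scale_um) ** 2
    f = math.sqrt(target_px2 / poly.area)
    return affinity.scale(poly, f, f, origin="centroid")


def random_lesion_rings(rng, center=(384.0, 384.0), r0=(60.0, 160.0)):
    """A random simple star-shaped ring for geometry oracle tests."""
    phi = np.linspace(0, 2 * math.pi, 512, endpoint=False)
    r = np.full_like(phi, rng.uniform(*r0))
    for k in range(2, 7):
        r += r * rng.normal(0, 0.05 / k) * np.cos(k * phi + rng.uniform(0, 2 * math.pi))
    return np.column_stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def circular_tracing():
    """Single circular lesion, radius 1000 um, centered at the FAF center."""
    poly = circle_polygon((383.5, 383.5), 1000.0 / PX_UM)
    return GATracing(components=(poly,), pixel_scale_um=PX_UM, filtered=True)
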