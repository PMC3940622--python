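import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hedgewalk as hw

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_landscape(rng):
    """A 60x60 landscape with 8 fields: small but structurally non-trivial."""
    return hw.generate_landscape(hw.LandscapeConfig(60, 60, 8), rng)


@pytest.fixture
def uniform_wild_landscape():
    """Single-habitat (all wild) landscape for kernel-only walk checks."""
    size = 201
    fields = np.zeros((size, size), dtype=int)
    habitat = np.full((size, size), hw.WILD, dtype=np.uint8)
    return hw.LandscapeGrid(size, size, fields, habitat)


def brute_force_assign(seeds, width, height):
    """Independent nearest-seed scan: per-cell loop, exact integer distances,
    lowest field_id wins ties. The oracle for the vectorised Voronoi path."""
    out = np.empty((height, width), dtype=int)
    ordered = sorted(seeds, key=lambda s: s.field_id)
    for y in range(height):
        for x in range(width):
            best_d, best_id = None, None
            for s in ordered:
                d = (x - s.x) ** 2 + (y - s.y) ** 2
                if best_d is None or d < best_d:
                    best_d, best_id = d, s.field_id
            out[y, x] = best_id
    return out
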