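import numpy as np
import pytest
from shapely.geometry import Point, box

from tamspatial.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Ten cases with full point patterns and geometries (seeded)."""
    return generate_cohort(SimulationConfig(n_cases=10, seed=42))


@pytest.fixture(scope="session")
def clinical_cohort():
    """Larger cohort without point patterns, for survival statistics."""
    return generate_cohort(
        SimulationConfig(n_cases=400, seed=7), include_cells=False
    )


@pytest.fixture
def disk_in_square():
    """Disk tumor (radius 200 um) centered in a 1400 um square ROI."""
    roi = box(0, 0, 1400, 1400)
    tumor = Point(700, 700).buffer(200, quad_segs=256)
    return roi, tumor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
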