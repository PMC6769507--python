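"""Shared fixtures: synthetic helices, slabs and posed frames."""

import numpy as np
import pytest

from pepmem import synthetic
from pepmem.synthetic import PoseSpec, RW16_SEQUENCE, SlabSpec


@pytest.fixture(scope="session")
def ideal_helix():
    return synthetic.build_ideal_helix(RW16_SEQUENCE)


@pytest.fixture(scope="session")
def standard_slab():
    return synthetic.build_slab(SlabSpec(), seed=7)


@pytest.fixture(scope="session")
def posed_frame(ideal_helix, standard_slab):
    """Helix at tilt 80 deg, azimuth 60 deg, depth 13 A in the upper leaflet."""
    pose = PoseSpec(tilt=80.0, azimuth=60.0, depth=13.0)
    return synthetic.place_helix(ideal_helix, standard_slab, pose)


@pytest.fixture(scope="session")
def flat_frame(ideal_helix, standard_slab):
    """Helix lying flat (tilt 90 deg) at 13 A."""
    pose = PoseSpec(tilt=90.0, azimuth=0.0, depth=13.0)
    return synthetic.place_helix(ideal_helix, standard_slab, pose)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
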