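"""Shared fixtures: ideal-geometry models, simulated maps, reference grids.

Everything is generated programmatically at test time; session scope keeps
the simulated maps and ensemble-built reference grids from being rebuilt in
every test.
"""

import numpy as np
import pytest

from emvalid.coords_only import default_cablam_references
from emvalid.restraints import RestraintLibrary
from emvalid.simulate import FixtureSpec, SimulationSpec, build_fixture, simulate_map


@pytest.fixture(scope="session")
def lib():
    return RestraintLibrary()


@pytest.fixture(scope="session")
def helix12():
    return build_fixture(FixtureSpec("helix", 12))


@pytest.fixture(scope="session")
def helix20():
    return build_fixture(FixtureSpec("helix", 20))


@pytest.fixture(scope="session")
def strand8():
    return build_fixture(FixtureSpec("strand", 8))


@pytest.fixture(scope="session")
def two_segment16():
    return build_fixture(FixtureSpec("two_segment", 16))


@pytest.fixture(scope="session")
def helix12_map(helix12):
    """Noise-free 2.3 Å map of the 12-residue helix."""
    return simulate_map(helix12, SimulationSpec(resolution=2.3, voxel_size=0.8,
                                                seed=11))


@pytest.fixture(scope="session")
def cablam_refs():
    return default_cablam_references(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
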