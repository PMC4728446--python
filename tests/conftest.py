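import numpy as np
import pytest
from hypothesis import settings

import spindlebridge as sb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from spindlebridge.solve import forward_consistent_case


@pytest.fixture(scope="session")
def hela_geometry():
    return sb.HELA_REFERENCE_GEOMETRY


@pytest.fixture(scope="session")
def hela_architecture():
    return sb.HELA_REFERENCE_ARCHITECTURE


@pytest.fixture(scope="session")
def hela_solution(hela_geometry, hela_architecture):
    """Inverse force-balance solve on the reference HeLa geometry (expensive;
    shared across tests)."""
    return sb.solve_force_balance(hela_geometry, hela_architecture)


@pytest.fixture(scope="session")
def consistent_case(hela_geometry, hela_architecture):
    """A self-consistent forward case (known loads and junction) whose
    constraint targets are exactly satisfied — ground truth for round trips."""
    geometry, loads, shape = forward_consistent_case(
        hela_geometry, hela_architecture, Fk_pN=300.0, xj_um=4.3
    )
    return geometry, loads, shape


@pytest.fixture(scope="session")
def reference_loads():
    """Load magnitudes of the published reference solution, used to exercise
    the forward model at realistic force scales."""
    return sb.BoundaryLoads(F0_pN=33.0, Fk_pN=280.0, M0_pN_um=0.0)
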