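import pytest
from hypothesis import settings

import ectsim as es

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tissues():
    return es.TissueTable()


@pytest.fixture(scope="session")
def tf():
    return es.TransferFunctionParams()


@pytest.fixture(scope="session")
def slab_mesh():
    """Default layered-slab phantom, shared across FEM tests."""
    return es.build_phantom(es.default_slab_spec())


@pytest.fixture(scope="session")
def small_slab_mesh():
    """Half-width slab with narrower pads, for cheap calibration tests."""
    spec = es.default_slab_spec(
        slab_size=(0.07, 0.063),
        patches=((0.007, 0.007, 0.021, 0.049), (0.042, 0.007, 0.021, 0.049)),
    )
    return es.build_phantom(spec)


@pytest.fixture(scope="session")
def tight_settings():
    """Solver settings tight enough for oracle comparisons."""
    return es.SolverSettings(
        linear_tolerance=1e-10, adaptive_tolerance=1e-6, max_adaptive_iterations=400
    )
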