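import numpy as np
import pytest

from elastoswim.meshes import HeadBody, make_flagellum_grid, make_head_mesh, make_wall


@pytest.fixture(scope="session")
def unit_sphere_mesh():
    """80-element unit sphere for quadrature cross-checks."""
    return make_head_mesh(1.0, 1.0, 1.0, refinement=1)


@pytest.fixture(scope="session")
def grid120():
    return make_flagellum_grid(120)


@pytest.fixture()
def rng():
    # fresh generator per test: draws must not depend on test ordering
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def sphere320_mesh():
    """320-element unit sphere for off-surface quadrature cross-checks."""
    return make_head_mesh(1.0, 1.0, 1.0, refinement=2)


@pytest.fixture(scope="session")
def sphere_resistance_1280():
    """Grand resistance matrix of a 1280-element unit sphere (mu = 1)."""
    from elastoswim.hydro import grand_resistance

    head = HeadBody((1.0, 1.0, 1.0), make_head_mesh(1, 1, 1, refinement=3))
    return grand_resistance(head, None, mu=1.0)
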