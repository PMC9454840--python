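import pytest
from hypothesis import settings

from wellfield import (
    convergence_study,
    default_chamber,
    generate_mesh,
    solve_potential,
)

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

#: default mesh resolution (m) for chamber solves in the suite
DEFAULT_EDGE = 0.5e-3


@pytest.fixture(scope="session")
def chamber():
    return default_chamber()


@pytest.fixture(scope="session")
def chamber_mesh(chamber):
    return generate_mesh(chamber, DEFAULT_EDGE)


@pytest.fixture(scope="session")
def field_1v(chamber_mesh):
    return solve_potential(chamber_mesh, 1.0)


@pytest.fixture(scope="session")
def convergence_table(chamber):
    """Midpoint field and per-depth current at 1.0 / 0.5 / 0.25 mm meshes."""
    return convergence_study(chamber, 1.0, [1.0e-3, 0.5e-3, 0.25e-3])
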