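import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gqm import (
    AffinityMatrix,
    Clone,
    Epitope,
    GeneratorConfig,
    Repertoire,
    generate_repertoire,
    solve_equilibrium,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Seed of the default natural-repertoire study fixture.
FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def natural_fixture(default_config):
    """Seeded natural repertoire with its solved equilibrium."""
    rep, mat = generate_repertoire(default_config)
    state = solve_equilibrium(rep, mat)
    return rep, mat, state


@pytest.fixture()
def two_by_two():
    """Tiny hand-built system: two clones sharing two epitopes.

    pK_D rows are (6, 4) and (4, 6), so the log-averaged internodal
    distance is exactly 2.0.
    """
    clones = {
        "cA": Clone(id="cA", ab_total=1e-9),
        "cB": Clone(id="cB", ab_total=2e-9),
    }
    epitopes = {
        "e0": Epitope(id="e0", ag_total=1e-6),
        "e1": Epitope(id="e1", ag_total=1e-6),
    }
    mat = AffinityMatrix(
        {
            ("cA", "e0"): 1e-6,
            ("cA", "e1"): 1e-4,
            ("cB", "e0"): 1e-4,
            ("cB", "e1"): 1e-6,
        }
    )
    return Repertoire(clones=clones, epitopes=epitopes), mat


def random_system(rng, max_clones=10, max_epitopes=10, density=None):
    """Random totals and K_D matrix, log-uniform over 1e-12..1e-4 M."""
    n = int(rng.integers(1, max_clones + 1))
    m = int(rng.integers(1, max_epitopes + 1))
    ab = 10.0 ** rng.uniform(-12, -4, n)
    ag = 10.0 ** rng.uniform(-12, -4, m)
    kd = 10.0 ** rng.uniform(-12, -4, (n, m))
    if density is None:
        density = rng.uniform(0.2, 1.0)
    kd = np.where(rng.uniform(size=(n, m)) < density, kd, np.inf)
    return ab, ag, kd
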