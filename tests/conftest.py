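import numpy as np
import pytest

from adbfsim.core import SystemState
from adbfsim.synthetic import BoxSpec, build_box


@pytest.fixture(scope="session")
def small_box() -> SystemState:
    """Equilibrium-ish 8-molecule periodic box (24 atoms)."""
    return build_box(BoxSpec(n_molecules=8, seed=11, relax_steps=100))


@pytest.fixture(scope="session")
def medium_box() -> SystemState:
    """20-molecule periodic box."""
    return build_box(BoxSpec(n_molecules=20, seed=12, relax_steps=100))


def random_state(rng: np.random.Generator, n_molecules: int = 4,
                 edge: float = 8.0) -> SystemState:
    """Random (not physical) water-like configuration for oracles."""
    M = n_molecules
    pos = rng.uniform(0, edge, (3 * M, 3))
    species = np.tile(["O", "H", "H"], M)
    masses = np.tile([16.0, 1.0, 1.0], M)
    mid = np.repeat(np.arange(M), 3)
    return SystemState(pos, np.zeros_like(pos), masses, species, mid,
                       np.full(3, edge), np.ones(3, bool))
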