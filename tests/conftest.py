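import numpy as np
import pytest

from chromolink.fiber import System, build_fiber, initialize_conformation
from chromolink.forcefield import default_force_field


@pytest.fixture(scope="session")
def ff():
    return default_force_field()


@pytest.fixture(scope="session")
def mono_state():
    return initialize_conformation(build_fiber(1, [], (0, 0)), mode="extended")


@pytest.fixture(scope="session")
def trinuc_system(ff):
    """A relaxed open trinucleosome system reused by analysis tests."""
    from chromolink.dynamics import minimize_system
    from chromolink.fiber import open_conformation

    topo = build_fiber(3, 30, (10, 10))
    system = System.from_fibers([open_conformation(topo, ff)])
    minimize_system(system, ff, 150.0, max_steps=50)
    return system


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
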