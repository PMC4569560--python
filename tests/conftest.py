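import numpy as np
import pytest

from adhesim.adhesion import BondTypeParams, KineticEnvironment

UM = 1.0e-6


@pytest.fixture
def lfa_icam() -> BondTypeParams:
    """Tabulated LFA-1 / ICAM-1 kinetic parameter set."""
    return BondTypeParams(
        "ICAM-1", "LFA-1", kon0=3000.0, koff0=0.3,
        spring=2.0e-3, transition_spring=1.0e-3, eq_length=0.05 * UM,
    )


@pytest.fixture
def mac_icam() -> BondTypeParams:
    """Tabulated Mac-1 / ICAM-1 kinetic parameter set."""
    return BondTypeParams(
        "ICAM-1", "Mac-1", kon0=3000.0, koff0=0.29,
        spring=2.0e-3, transition_spring=1.0e-3, eq_length=0.05 * UM,
    )


@pytest.fixture
def env() -> KineticEnvironment:
    """Body-temperature environment with zero microvilli standoff."""
    return KineticEnvironment(temperature=310.15, dt=1.0e-3, eps_mv=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def approach_with_repulsion():
    """Driven approach of the TC onto the PMN, repulsion active (shared:
    the settling run takes a few seconds)."""
    from adhesim import fixtures as fx

    return fx.driven_approach(n_steps=900)


@pytest.fixture(scope="session")
def approach_without_repulsion():
    from adhesim import fixtures as fx

    return fx.driven_approach(repulsion=False, n_steps=900)
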