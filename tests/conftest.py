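import numpy as np
import pytest

from ribocomp import CellInputs, KineticParams, PopulationMoments


@pytest.fixture(scope="session")
def kinetics():
    return KineticParams()


@pytest.fixture(scope="session")
def base_cell():
    return CellInputs()


@pytest.fixture(scope="session")
def base_moments():
    return PopulationMoments()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_model(rng):
    """A random valid (kinetics, cell) pair spanning wide parameter ranges."""
    kin = KineticParams(
        n1=rng.uniform(1, 50), n2=rng.uniform(1, 50),
        beta1=10 ** rng.uniform(0, 4), beta2=10 ** rng.uniform(0, 4),
    )
    cell = CellInputs(
        M1T=10 ** rng.uniform(0, 3), M2T=10 ** rng.uniform(0, 3),
        RibT=10 ** rng.uniform(3, 4.5),
    )
    return kin, cell
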