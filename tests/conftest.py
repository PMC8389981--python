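import numpy as np
import pytest

from nanoshs import NanoparticleSpec, SolutionConditions


@pytest.fixture
def water_1mM():
    """Reference conditions: 1:1 electrolyte, 1 mM, 298.15 K, eps_r 78.4."""
    return SolutionConditions()


@pytest.fixture
def ps100(water_1mM):
    """100 nm plain polystyrene particle at SHS working number density."""
    return NanoparticleSpec(
        diameter=100e-9, number_density=4.55e14, zeta_potential=-42e-3, label="PS"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
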