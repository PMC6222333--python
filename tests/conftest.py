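import numpy as np
import pytest

import cvstring as cs


@pytest.fixture(scope="session")
def muller_brown_surface():
    return cs.muller_brown()


@pytest.fixture(scope="session")
def mb_minima(muller_brown_surface):
    """The two lowest minima of the benchmark landscape, Newton-polished."""
    mb = muller_brown_surface
    return (
        cs.refine_minimum(mb, [-0.55, 1.44]),
        cs.refine_minimum(mb, [0.62, 0.03]),
    )


@pytest.fixture(scope="session")
def mb_oracle(muller_brown_surface, mb_minima):
    return cs.brute_force_mep(muller_brown_surface, *mb_minima, resolution=0.01)


@pytest.fixture(scope="session")
def room_kT():
    return cs.thermal_energy(298.0)
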