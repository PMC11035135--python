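import numpy as np
import pytest

from reporterdiff.synth import Compartment, PelletPhantomSpec, make_pellet_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_two_compartment():
    """Noiseless pellet phantom with D = 1.0 and 2.0 µm²/ms disks."""
    spec = PelletPhantomSpec(
        shape=(64, 64),
        compartments=[Compartment((20, 32), 9, 1.0),
                      Compartment((45, 32), 9, 2.0)],
        noise="none",
    )
    series, truth = make_pellet_phantom(spec)
    return spec, series, truth
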