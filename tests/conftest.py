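import numpy as np
import pytest

from kdrkit import ephys, synthgen


@pytest.fixture(scope="session")
def protocol():
    return ephys.VoltageProtocol()


@pytest.fixture(scope="session")
def channel_spec():
    return synthgen.ChannelSimSpec()


@pytest.fixture(scope="session")
def sequence_spec():
    return synthgen.SequenceSimSpec(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250918)


@pytest.fixture(scope="session")
def table1_design():
    """Adult susceptible deltamethrin bioassay design: slope 5.3, LC50 7.6e-6,
    five concentrations spanning 5-95% mortality, ~134 adults per dose."""
    lc50, slope = 7.6e-6, 5.3
    return dict(
        true_lc50=lc50,
        true_slope=slope,
        concentrations=synthgen.design_spanning(lc50, slope),
        n_per_conc=134,
    )
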