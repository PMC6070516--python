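import numpy as np
import pytest

import swayrqa as sq


@pytest.fixture(scope="session")
def protocol():
    return sq.default_protocol()


@pytest.fixture(scope="session")
def platform(protocol):
    return sq.generate_platform(protocol)


@pytest.fixture(scope="session")
def trial(protocol, platform):
    """One default synthetic trial (platform, com) at seed 0."""
    com = sq.generate_com(platform, protocol, sq.CouplingParams(seed=0))
    return platform, com


def sinusoid(freq=1.0, fs=100.0, duration=10.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return sq.TimeSeries(amplitude * np.sin(2 * np.pi * freq * t + phase), fs=fs)
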