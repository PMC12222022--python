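import numpy as np
import pytest

from nociscope.protocol import ProtocolConfig, make_protocol
from nociscope.simulate import sample_population


@pytest.fixture(scope="session")
def default_protocol():
    return make_protocol()


@pytest.fixture(scope="session")
def small_population():
    return sample_population(40, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_kernel_trace(n, fs, events, noise_sd=0.0, rng=None, rise=0.15, decay=1.0):
    """Place unit-peak kernels scaled by amplitude at given (time, amp) pairs."""
    from nociscope.simulate import transient_kernel

    t = np.arange(n) / fs
    x = np.zeros(n)
    for t0, amp in events:
        sel = t >= t0
        x[sel] += amp * transient_kernel(t[sel] - t0, rise, decay)
    if noise_sd > 0:
        x += rng.normal(0, noise_sd, n)
    return t, x
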