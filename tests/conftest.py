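import numpy as np
import pytest

from mtconform.io_formats import DEFAULT_DELAYS_MS
from mtconform.relaxation import RelaxationSeries
from mtconform.synthetic import stylommatophora_lineage


@pytest.fixture(scope="session")
def delays():
    return np.asarray(DEFAULT_DELAYS_MS)


@pytest.fixture
def noiseless_series(delays):
    """Exact exponential decay: I0=100, T2=120 ms at the nine CPMG delays."""
    return RelaxationSeries("ref", delays, 100.0 * np.exp(-delays / 120.0))


def make_noisy_series(delays, i0=50.0, t2=80.0, sigma_fraction=0.02, rng=None):
    rng = rng or np.random.default_rng(0)
    clean = i0 * np.exp(-delays / t2)
    return RelaxationSeries(
        "noisy", delays, clean + rng.normal(0, sigma_fraction * i0, delays.size)
    )


@pytest.fixture(scope="session")
def lineage():
    """The deterministic synthetic snail-MT lineage fixture."""
    return stylommatophora_lineage()
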