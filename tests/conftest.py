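import numpy as np
import pytest

from fastecho import (
    Excitation,
    Medium,
    build_linear_array,
    element_quadrature,
)


@pytest.fixture(scope="session")
def medium():
    return Medium(sound_speed=1540.0, density=1000.0)


@pytest.fixture(scope="session")
def array128():
    return build_linear_array(128, 0.3e-3, 7.0e-3, 0.05e-3)


@pytest.fixture(scope="session")
def array8():
    return build_linear_array(8, 0.3e-3, 7.0e-3, 0.05e-3)


@pytest.fixture(scope="session")
def pulse_3mhz():
    return Excitation(f0=3.0e6, n_cycles=1)


@pytest.fixture(scope="session")
def quad128(array128):
    return element_quadrature(array128)


def embed_pair(w1, w2):
    """Embed two waveforms on their union lattice for comparison."""
    s = min(w1.start, w2.start)
    e = max(w1.start + len(w1.data), w2.start + len(w2.data))
    a = np.zeros(e - s)
    b = np.zeros(e - s)
    a[w1.start - s : w1.start - s + len(w1.data)] = w1.data
    b[w2.start - s : w2.start - s + len(w2.data)] = w2.data
    return a, b


def waveform_nrmse(w1, w2):
    a, b = embed_pair(w1, w2)
    return float(np.sqrt(np.sum((a - b) ** 2) / np.sum(b**2)))
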