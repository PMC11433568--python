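import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A generic 32x32 float image with intensities in [0, 255]."""
    return rng.uniform(0.0, 255.0, size=(32, 32))


def all_bit_patterns():
    """All 256 possible 8-bit patterns as arrays of {0,1}."""
    for code in range(256):
        yield np.array([(code >> i) & 1 for i in range(8)], dtype=np.int64)


def brute_force_riu2(bits):
    """Independent riu2 oracle: count circular transitions by explicit loop."""
    b = list(bits)
    transitions = sum(abs(b[i] - b[(i + 1) % 8]) for i in range(8))
    return sum(b) if transitions <= 2 else 9
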