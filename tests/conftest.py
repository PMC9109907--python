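import numpy as np
import pytest

import phagoscreen as ps


@pytest.fixture(scope="session")
def benzene():
    return ps.parse_smiles("c1ccccc1")


@pytest.fixture(scope="session")
def tiny_library():
    """Forty generated compounds, fixed seed (session-wide, read-only)."""
    return ps.generate_library(40, seed=5)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_library):
    """Noise-free planted screen over the tiny library, deduplicated."""
    records = ps.plant_screen(tiny_library, ps.default_rules(noise_rate=0.0), seed=5)
    return ps.build_dataset(records)


def random_fingerprint(rng, length=64, density=0.3):
    bits = (rng.random(length) < density).astype(np.uint8)
    if not bits.any():
        bits[rng.integers(length)] = 1
    return ps.Fingerprint(bits, radius=3, length=length)
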