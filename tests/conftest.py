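import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from psarp.simdata import SimConfig, default_nested, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Small error-free study with nested co-amplification: 3 samples,
    6 alleles per gene."""
    cfg = SimConfig(
        n_samples=3,
        pool_sizes={"A": 6, "B": 6, "C": 6, "H": 6},
        nested_amplification=default_nested(),
        long_mismatch=0.0,
        long_insertion=0.0,
        long_deletion=0.0,
        short_error=0.0,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same geometry with the default error model."""
    cfg = SimConfig(
        n_samples=3,
        pool_sizes={"A": 6, "B": 6, "C": 6, "H": 6},
        nested_amplification=default_nested(),
        seed=12,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_seq(rng, n):
    return rng.choice(np.frombuffer(b"ACGT", np.uint8), size=n).tobytes().decode()
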