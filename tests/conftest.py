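import numpy as np
import pytest

from peakscape.simulate import SyntheticConfig, simulate_dataset


def small_config(**overrides) -> SyntheticConfig:
    """A reduced synthetic genome for fast unit tests."""
    base = dict(
        seed=0,
        n_chroms=2,
        chrom_length=3_500_000,
        n_genes=80,
        n_peaks=300,
        n_se_clusters=(3, 2, 2),
        n_motifs=10,
        motif_members=40,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated experiment shared across unit tests."""
    return simulate_dataset(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
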