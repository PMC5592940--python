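import numpy as np
import pytest

from draftkit import simulate

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_truth():
    """100-kb genome with two diverged repeat families (shared across tests)."""
    return simulate.generate_repeat_genome(
        100_000, repeat_fraction=0.2, n_families=2, copies_per_family=2,
        divergence=0.1, seed=101,
    )


@pytest.fixture(scope="session")
def small_reads(small_truth):
    return simulate.simulate_paired_reads(small_truth, coverage=30, seed=102)
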