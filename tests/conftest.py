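import numpy as np
import pytest

from poolfreqtest import LocusTable


@pytest.fixture
def rng():
    return np.random.default_rng(20170615)


@pytest.fixture
def table1():
    """The motivating 2x2x3 example: a significant CMH result whose
    allele-frequency difference flips direction in the third replicate."""
    counts_a = np.array([[66, 90], [72, 60], [69, 6]])
    coverage = np.array([[66 + 5, 90 + 3], [72 + 3, 60 + 5], [69 + 21, 6 + 72]])
    return LocusTable(counts_a=counts_a, coverage=coverage)


def make_random_tables(n_tables: int = 50, seed: int = 11, k_range=(2, 5),
                       min_count: int = 1):
    """Seeded random 2x2xk tables with all cells >= min_count, so the
    zero-cell rule is the identity and oracle comparisons are exact."""
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_tables):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        coverage = rng.integers(20, 400, size=(k, 2))
        counts_a = rng.binomial(coverage, rng.uniform(0.05, 0.95))
        counts_a = np.clip(counts_a, min_count, coverage - min_count)
        tables.append(LocusTable(counts_a=counts_a, coverage=coverage))
    return tables


@pytest.fixture(scope="session")
def random_tables():
    return make_random_tables()
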