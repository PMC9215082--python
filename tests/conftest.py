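"""Shared helpers for the test suite."""

import numpy as np
import pytest

from dcmscan.core import HaplotypeMatrix


def random_matrix(rng, n_sites=30, n_samples=4, chrom="1", missing_rate=0.0,
                  max_pos=100_000):
    """Random biallelic HaplotypeMatrix with strictly increasing positions."""
    n_hap = 2 * n_samples
    positions = np.sort(rng.choice(np.arange(1, max_pos + 1), size=n_sites,
                                   replace=False))
    alleles = rng.integers(0, 2, size=(n_sites, n_hap)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n_sites, n_hap)) < missing_rate
        # keep at least one call per site
        mask[mask.all(axis=1), 0] = False
        alleles[mask] = -1
    ids = [f"S{i:03d}" for i in range(n_samples)]
    return HaplotypeMatrix(chrom, positions, alleles, ids)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
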