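import numpy as np
import pytest

from regscan.intervals import ChromSizes, GenomeInterval
from regscan.synthetic import make_bundle


@pytest.fixture(scope="session")
def bundle():
    """One deterministic fixture genome shared by the slower tests."""
    return make_bundle(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_intervals(rng, n, chrom="chrA", size=10_000, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, size - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomeInterval(chrom, start, min(start + length, size)))
    return out


def bitmap(intervals, size, chrom="chrA"):
    """Per-base boolean-array oracle for interval sets."""
    arr = np.zeros(size, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            arr[iv.start:iv.end] = True
    return arr
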