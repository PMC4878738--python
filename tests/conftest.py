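import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chrombound.core_intervals import GenomeAssembly, GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20160524)


@pytest.fixture
def toy_assembly():
    """100 kb chromosome with two gaps."""
    return GenomeAssembly(
        {"chr1": 100_000},
        gaps=[GenomicInterval("chr1", 20_000, 22_000), GenomicInterval("chr1", 60_000, 61_000)],
    )


def random_interval_rows(rng, n, chroms=("chr1", "chr2"), size=100_000, max_len=2_000):
    starts = rng.integers(0, size - max_len, n)
    lengths = rng.integers(1, max_len, n)
    cs = rng.choice(chroms, n)
    return [(str(cs[i]), int(starts[i]), int(starts[i] + lengths[i])) for i in range(n)]


def rows_to_set(rows, label=""):
    return IntervalSet.from_arrays(
        [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows], label=label
    )
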