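import numpy as np
import pandas as pd
import pytest

from calq.intervals import Genome, IntervalSet
from calq.simulate import default_target_genome, make_fixture_annotations


@pytest.fixture
def toy_genome():
    return Genome({"chr1": 1000, "chr2": 500})


@pytest.fixture(scope="session")
def target_genome():
    return default_target_genome()


@pytest.fixture(scope="session")
def fixture_annotations(target_genome):
    return make_fixture_annotations(target_genome, n_genes=1000, seed=7)


def random_interval_set(rng, n, chroms=("chr1", "chr2"), max_pos=1000, max_len=100):
    starts = rng.integers(0, max_pos, n)
    lengths = rng.integers(1, max_len, n)
    return IntervalSet(
        pd.DataFrame(
            {
                "chrom": rng.choice(chroms, n),
                "start": starts,
                "end": starts + lengths,
            }
        )
    )


def brute_force_overlaps(a: IntervalSet, b: IntervalSet, min_bp=1):
    out = np.zeros(len(a), dtype=bool)
    for i, ra in enumerate(a.df.itertuples(index=False)):
        for rb in b.df.itertuples(index=False):
            if ra.chrom == rb.chrom and min(ra.end, rb.end) - max(ra.start, rb.start) >= min_bp:
                out[i] = True
                break
    return out
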