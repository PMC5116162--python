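import random

import pytest

from sgatools import SgaRecord, SgaStream, sort_records


def random_records(rng, n, chroms=("chr1", "chr2"), features=("R", "T"),
                   max_pos=5000, max_count=4, strands=("+", "-", "0"),
                   with_extras=False):
    """A random unsorted record list over a small coordinate space."""
    records = []
    for i in range(n):
        extras = (f"x{i}",) if with_extras and rng.random() < 0.5 else ()
        records.append(SgaRecord(
            rng.choice(chroms), rng.choice(features),
            rng.randint(1, max_pos), rng.choice(strands),
            rng.randint(1, max_count), extras))
    return records


def sorted_stream(records):
    return sort_records(SgaStream(records))


@pytest.fixture
def rng():
    return random.Random(20161118)


@pytest.fixture
def small_sorted(rng):
    records = random_records(rng, 100)
    return sort_records(SgaStream(records)).to_list()
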