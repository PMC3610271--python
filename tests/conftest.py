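import numpy as np
import pandas as pd
import pytest

from chiptools import GenomeTable, TagCollection, SimulationParams


@pytest.fixture
def genome():
    return GenomeTable((("chr1", 100_000), ("chr2", 50_000)))


@pytest.fixture
def big_genome():
    return GenomeTable((("chr1", 10_000_000),))


def make_tags(records, genome):
    """TagCollection from (chrom, pos, strand[, count]) tuples."""
    return TagCollection.from_records(records, genome)


@pytest.fixture
def sim_params():
    """Small, fast simulation for unit tests."""
    return SimulationParams(genome_length=200_000, n_chroms=1, seed=1,
                            n_planted_sites=40)
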