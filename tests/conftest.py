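import numpy as np
import pytest

from cutkit.anchor import ExactMatchIndex
from cutkit.enzymes import NLAIII, SiteIndex
from cutkit.simulate import generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """100-kb single-chromosome i.i.d. genome (fixed seed)."""
    return generate_genome({"chr1": 100_000}, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def nla_index(small_genome):
    return SiteIndex.from_sequences(small_genome.sequences, NLAIII)


@pytest.fixture(scope="session")
def match_index(small_genome):
    return ExactMatchIndex(small_genome.sequences)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
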