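import numpy as np
import pytest

from cpg_mutspec.core import GenomeSequence
from cpg_mutspec.synthetic import generate_annotations, generate_genome


@pytest.fixture
def tiny_genome():
    # hand-written contig: positions are easy to reason about
    #            123456789012345678901234
    return GenomeSequence({"c1": "ACGTACGTCCGGAAATTTCGCGAT"})


@pytest.fixture(scope="session")
def medium_genome():
    return generate_genome(200_000, gc_fraction=0.5, cpg_obs_exp=1.0, seed=101)


@pytest.fixture(scope="session")
def medium_annotations(medium_genome):
    return generate_annotations(
        medium_genome,
        fractions={"sine": 0.10, "line": 0.05, "ltr": 0.02, "cgi": 0.02,
                   "dmr": 0.05, "simple_repeat": 0.005},
        n_genes=8,
        seed=102,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
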