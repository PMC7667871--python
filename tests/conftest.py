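import numpy as np
import pytest

from clipflow._kmer import KmerIndex
from clipflow.io_formats import Genome
from clipflow.synthetic_data import (
    GroundTruthManifest,
    build_annotation,
    build_genome,
)


@pytest.fixture(scope="session")
def genome50k():
    return build_genome(seed=1, length=50_000)


@pytest.fixture(scope="session")
def genes50k(genome50k):
    return build_annotation(genome50k, seed=2, n_genes=20, operon_fraction=0.3)


@pytest.fixture(scope="session")
def index50k(genome50k):
    return KmerIndex(genome50k)


@pytest.fixture(scope="session")
def genome5k():
    return build_genome(seed=11, length=5_000)


@pytest.fixture()
def manifest():
    return GroundTruthManifest(seed=1)


def random_genome(seed: int, length: int) -> Genome:
    """Plain random genome without the builder, for oracle independence."""
    rng = np.random.default_rng(seed)
    return Genome({"chr": "".join(rng.choice(list("ACGT"), size=length))})
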