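import numpy as np
import pytest
from hypothesis import settings

import geosig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from geosig.tsvq import sample_seed


@pytest.fixture(scope="session")
def table4():
    """Standard 4-mer table (256 x 136), fixed seed."""
    return geosig.build_signature_table(4, seed=11)


@pytest.fixture(scope="session")
def table2():
    """Small 2-mer table for cheap exact checks."""
    return geosig.build_signature_table(2, N=10, seed=11)


@pytest.fixture(scope="session")
def small_collection(table4):
    """Well-separated 3-city collection of fitted TSVQ trees.

    3 cities x 4 samples x 600 reads at separation 1; order 4, depth 2.
    Session-scoped: several tests share it read-only.
    """
    coll = geosig.generate_collection(
        n_cities=3, samples_per_city=4, n_reads=600, separation=1.0, seed=5
    )
    trees = []
    for sid, loc, city, reads in coll.samples:
        m = geosig.sample_to_matrix(reads, table4, sample_id=sid)
        tree = geosig.tsvq_fit(m, order=4, depth=2, seed=sample_seed(5, sid))
        trees.append((tree, loc, city))
    return trees


@pytest.fixture(scope="session")
def small_library(small_collection):
    return geosig.build_library(small_collection, level=2, k=4)
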