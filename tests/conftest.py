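import logging

import numpy as np
import pytest

from popgen.io import GenotypeMatrix, SampleMeta, SnpLocus

logging.getLogger("popgen").setLevel(logging.ERROR)


def make_matrix(calls, pops=None, lats=None, lons=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list of calls (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    pops = pops or [f"pop{i + 1}" for i in range(n)]
    samples = [
        SampleMeta(
            accession_id=f"s{i + 1}",
            population_id=pops[i],
            latitude=(lats[i] if lats else float("nan")),
            longitude=(lons[i] if lons else float("nan")),
        )
        for i in range(n)
    ]
    loci = [SnpLocus(id=f"L{j + 1}", chromosome="1", position=j + 1) for j in range(L)]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


@pytest.fixture
def toy_matrix():
    """3 samples x 2 loci, complete calls."""
    return make_matrix([[0, 1], [1, 0], [0, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
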