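import numpy as np
import pytest

from cgreg.genotype_io import GenotypeMatrix, PopulationLabels


def make_matrix(counts, marker_ids=None, individual_ids=None, alleles=True):
    counts = np.asarray(counts, dtype=np.int16)
    m, n = counts.shape
    marker_ids = marker_ids or [f"m{i}" for i in range(m)]
    individual_ids = individual_ids or [f"ind{j}" for j in range(n)]
    labels = [("A", "B")] * m if alleles else None
    return GenotypeMatrix(marker_ids, individual_ids, counts, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def two_pop_reference():
    """Six labeled individuals, two populations, four markers."""
    counts = np.array(
        [
            [0, 1, 2, 2, 2, 2],
            [0, 0, 0, 2, 1, 2],
            [1, 1, 1, 0, 0, 0],
            [2, 2, 2, 0, 1, 0],
        ]
    )
    geno = make_matrix(counts)
    labels = PopulationLabels.from_pairs(
        [(f"ind{j}", "A" if j < 3 else "B") for j in range(6)]
    )
    return geno, labels
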