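import numpy as np
import pytest

from microbiogeo.io import read_tree_string
from microbiogeo.types import OTUTable


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the worked example used throughout."""
    return read_tree_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table():
    counts = np.array([[3, 0, 1],
                       [1, 2, 0],
                       [0, 1, 4]])
    return OTUTable(counts, ["S1", "S2", "S3"], ["A", "B", "C"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_table(rng, n_samples, n_otus, max_count=20, ensure_positive=True):
    counts = rng.integers(0, max_count + 1, size=(n_samples, n_otus))
    if ensure_positive:
        for i in range(n_samples):
            if counts[i].sum() == 0:
                counts[i, rng.integers(n_otus)] = 1
    return OTUTable(counts,
                    [f"S{i}" for i in range(n_samples)],
                    [f"OTU_{j:05d}" for j in range(n_otus)])
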