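import numpy as np
import pytest

from modref.containers import LabeledCounts
from modref.simulate import SyntheticConfig, generate_paired


def small_counts(n_cells=12, n_genes=5, seed=0, modality="cell",
                 types=("A", "B")):
    rng = np.random.default_rng(seed)
    return LabeledCounts(
        values=rng.integers(0, 20, size=(n_cells, n_genes)),
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        cell_type=np.array([types[i % len(types)] for i in range(n_cells)],
                           dtype=object),
        modality=np.array([modality] * n_cells, dtype=object),
        donor=np.array([f"d{i % 2}" for i in range(n_cells)], dtype=object),
    )


@pytest.fixture
def lc_small():
    return small_counts()


@pytest.fixture(scope="session")
def tiny_config():
    """A fast paired-data configuration for unit tests."""
    return SyntheticConfig(
        n_genes=300,
        cell_types=(("typeA", 80, 80), ("typeB", 60, 60), ("typeC", 50, 50)),
        n_markers_per_type=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_pair(tiny_config):
    return generate_paired(tiny_config)
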