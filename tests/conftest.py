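import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from osmohet import PipelineConfig
from osmohet.data import CountDataset


@pytest.fixture
def cfg():
    return PipelineConfig()


def make_dataset(counts, gene_ids=None, cell_ids=None, meta=None):
    """Build a CountDataset from a dense array and optional ids/metadata."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(n_cells)]
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(n_genes)]
    if meta is None:
        meta = pd.DataFrame(index=cell_ids)
    return CountDataset(counts=sp.csr_matrix(counts), cell_ids=cell_ids,
                        gene_ids=gene_ids, cell_meta=meta)


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(0)
    return make_dataset(rng.poisson(2.0, size=(20, 30)))
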