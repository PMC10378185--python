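import numpy as np
import pandas as pd
import pytest
from anndata import AnnData


@pytest.fixture
def rng():
    return np.random.default_rng(20230714)


def make_adata(X, genes=None, cells=None) -> AnnData:
    """Build a cells x genes AnnData from a dense array."""
    X = np.asarray(X, dtype=float)
    n_cells, n_genes = X.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(n_cells)]
    return AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
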