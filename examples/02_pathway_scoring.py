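"""Score per-cell gene-set activity with the rank-AUC statistic.

Builds a small synthetic expression matrix in which one gene set is
upregulated in half the cells, scores every cell, and summarizes activity
per cell line and cell-cycle phase.
"""

import numpy as np
import pandas as pd

from clonesteer import GeneSet, aucell_scores, filter_cells, median_activity_by_group
from anndata import AnnData

rng = np.random.default_rng(0)
n_cells, n_genes = 200, 1000
genes = [f"g{i}" for i in range(n_genes)]
X = rng.poisson(1.0, size=(n_cells, n_genes)).astype(float)
active = np.arange(n_cells) < 100  # first half of the cells
X[np.ix_(active, np.arange(20))] += rng.poisson(4.0, size=(100, 20))

adata = AnnData(
    X=X,
    obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
    var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
)
adata = filter_cells(adata, min_features=200)

signature = GeneSet("signature", tuple(genes[:20]))
control = GeneSet("control", tuple(genes[500:520]))
activity = aucell_scores(adata, [signature, control], top_fraction=0.05)

ann = pd.DataFrame(
    {
        "cell_id": adata.obs_names,
        "cell_line": np.where(active[: adata.n_obs], "active_line", "baseline_line"),
        "clone_id": "clone0",
        "phase": rng.choice(["G0G1", "S", "G2M"], adata.n_obs, p=[0.6, 0.2, 0.2]),
    }
)
medians = median_activity_by_group(activity, ann, "all")
print("median activity per cell line (top 5% rank-AUC, range 0-1):")
print(medians.round(3))
print(
    "\nThe upregulated line should show clearly higher 'signature' activity,"
    "\nwhile 'control' stays near the baseline in both lines: the score is"
    "\nrank-based, so library size and normalization do not matter."
)
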