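"""Rank-based gene-set activity scoring per cell (an AUCell-style statistic).

For every cell, genes are ranked by decreasing expression and a recovery curve
is built: the number of gene-set members found among the top ``x`` ranked
genes for ``x = 1 .. ceil(top_fraction * n_genes)`` (genes in the top 5% of
the ranking count as "active" by default).  The activity score is the area
under this curve normalized by the ideal recovery curve for the same set size
and threshold, so a perfectly top-ranked set scores 1 and a set absent from
the top fraction scores 0.  Because only ranks matter, the score is invariant
to any monotone transform of a cell's expression values, hence insensitive to
units or normalization.

All cell lines are scored together in one joint matrix; no further batch
correction is applied.  Expression ties are broken by a random permutation
drawn once per cell from a fixed-seed generator so results are deterministic.

The expression container is :class:`anndata.AnnData` (cells x genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from anndata import AnnData

from .errors import EmptyMatrixError, InvalidParameterError

PHASES = ("G0G1", "S", "G2M")
GROUPINGS = ("G0G1", "S", "G2M", "all")

#: Default seed of the tie-breaking permutation generator.
DEFAULT_TIE_SEED = 42


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene IDs (members need not all be measured)."""

    name: str
    genes: tuple

    def __post_init__(self):
        if not self.name or len(self.genes) == 0:
            raise InvalidParameterError("gene set needs a name and >= 1 member")
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def filter_cells(adata: AnnData, min_features: int = 200) -> AnnData:
    """Keep cells expressing at least ``min_features`` genes (count > 0).

    A cell with exactly ``min_features`` detected genes is kept; cells with
    fewer are excluded.  Removing every cell raises :class:`EmptyMatrixError`.
    """
    X = _dense(adata)
    detected = (X > 0).sum(axis=1)
    keep = detected >= min_features
    if not np.any(keep):
        raise EmptyMatrixError(
            f"no cell has >= {min_features} detected features; 0 of {adata.n_obs} kept"
        )
    return adata[keep].copy()


def _normalize_sets(gene_sets) -> list[GeneSet]:
    if isinstance(gene_sets, GeneSet):
        return [gene_sets]
    if isinstance(gene_sets, Mapping):
        return [GeneSet(name, tuple(genes)) for name, genes in gene_sets.items()]
    return list(gene_sets)


def aucell_scores(
    adata: AnnData,
    gene_sets,
    top_fraction: float = 0.05,
    tie_seed: int = DEFAULT_TIE_SEED,
) -> pd.DataFrame:
    """Score every cell for every gene set; returns cells x sets in [0, 1].

    ``gene_sets`` may be a :class:`GeneSet`, a sequence of them, or a mapping
    of name -> gene IDs.  A set with no member present in the matrix scores 0
    for every cell, with a warning.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise EmptyMatrixError("expression matrix is empty")
    if not 0 < top_fraction <= 1:
        raise InvalidParameterError("top_fraction must be in (0, 1]")
    sets = _normalize_sets(gene_sets)
    X = _dense(adata)
    n_cells, n_genes = X.shape
    top = int(np.ceil(top_fraction * n_genes))

    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    members = np.zeros((len(sets), n_genes), dtype=bool)
    max_area = np.empty(len(sets))
    x_grid = np.arange(1, top + 1)
    for s, gs in enumerate(sets):
        idx = [gene_index[g] for g in gs.genes if g in gene_index]
        members[s, idx] = True
        m = len(idx)
        if m == 0:
            warnings.warn(
                f"gene set {gs.name!r} has no member in the matrix; scores set to 0",
                stacklevel=2,
            )
            max_area[s] = np.inf  # area is 0, score 0/inf -> 0
        else:
            max_area[s] = np.minimum(x_grid, m).sum()

    rng = np.random.default_rng(tie_seed)
    scores = np.empty((n_cells, len(sets)))
    for i in range(n_cells):
        tiebreak = rng.permutation(n_genes)
        order = np.lexsort((tiebreak, -X[i]))
        hits = members[:, order[:top]]  # sets x top
        area = np.cumsum(hits, axis=1).sum(axis=1)
        scores[i] = area / max_area
    return pd.DataFrame(
        scores, index=adata.obs_names.copy(), columns=[gs.name for gs in sets]
    )


def aucell_score(
    adata: AnnData,
    gene_set: GeneSet,
    top_fraction: float = 0.05,
    tie_seed: int = DEFAULT_TIE_SEED,
) -> pd.Series:
    """Per-cell activity of a single gene set (column of :func:`aucell_scores`)."""
    return aucell_scores(adata, [gene_set], top_fraction, tie_seed).iloc[:, 0]


def median_activity_by_group(
    activity: pd.DataFrame,
    annotations: pd.DataFrame,
    grouping: str = "all",
) -> pd.DataFrame:
    """Median activity per (cell line, gene set) over cells of one cell-cycle
    phase (or all phases combined).

    ``annotations`` must carry columns ``cell_id``, ``cell_line`` and
    ``phase``.  Cell lines with no cell in the requested group are absent from
    the output, with a warning.
    """
    if grouping not in GROUPINGS:
        raise InvalidParameterError(f"grouping must be one of {GROUPINGS}")
    ann = annotations.set_index("cell_id") if "cell_id" in annotations.columns else annotations
    common = activity.index.intersection(ann.index)
    act = activity.loc[common]
    ann = ann.loc[common]
    if grouping != "all":
        mask = (ann["phase"] == grouping).to_numpy()
        act, ann = act.loc[mask], ann.loc[mask]
    all_lines = set(annotations["cell_line"]) if "cell_line" in annotations.columns else set()
    out = act.groupby(ann["cell_line"], observed=True).median()
    missing = all_lines - set(out.index)
    if missing:
        warnings.warn(
            f"no {grouping} cells for cell line(s) {sorted(missing)}; absent from output",
            stacklevel=2,
        )
    out.index.name = "cell_line"
    return out
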