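"""Linear transcriptomic biomarkers of growth rate and carrying capacity.

Each candidate biomarker is an ordinary least-squares model

    delta ~ a * p + c,

where ``delta`` is a growth parameter (r or K) fitted per cell line from its
growth curve and ``p`` is the cell line's median activity of one gene set
within one cell-cycle grouping.  Candidates are ranked by adjusted R^2 and the
top few are carried into a validation refit on the full cell-line cohort with
Benjamini-Hochberg FDR control applied per target parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError
from .growth_fitting import adjusted_r2

TARGETS = ("r", "K")


@dataclass
class BiomarkerModel:
    """A fitted linear map from pathway activity to a growth parameter."""

    gene_set: str
    target: str  # "r" or "K"
    grouping: str  # cell-cycle grouping the activity medians came from
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n_obs: int
    degenerate: bool = False
    fdr_q: float | None = None
    confirmed: bool | None = None

    def predict(self, activity):
        if self.degenerate:
            raise InvalidParameterError(
                f"degenerate biomarker {self.gene_set}/{self.grouping} cannot predict"
            )
        return self.slope * np.asarray(activity, dtype=float) + self.intercept


def fit_biomarker(
    activity: pd.Series,
    targets: pd.Series,
    gene_set: str = "",
    target: str = "r",
    grouping: str = "all",
) -> BiomarkerModel:
    """OLS fit of per-cell-line growth-parameter values on activity medians.

    ``activity`` and ``targets`` are aligned on their (cell line) index; at
    least 3 paired observations are required.  Zero variance in activity
    yields a model flagged ``degenerate`` (excluded from ranking downstream).
    """
    common = activity.index.intersection(targets.index)
    x = activity.loc[common].to_numpy(dtype=float)
    y = targets.loc[common].to_numpy(dtype=float)
    n = len(common)
    if n < 3:
        raise InvalidParameterError(f"need >= 3 paired observations, got {n}")
    if np.ptp(x) == 0.0:
        return BiomarkerModel(
            gene_set, target, grouping,
            slope=np.nan, intercept=np.nan, pearson_r=np.nan, r_squared=np.nan,
            adj_r_squared=np.nan, p_value=np.nan, n_obs=n, degenerate=True,
        )
    res = linregress(x, y)
    r2 = res.rvalue**2
    return BiomarkerModel(
        gene_set=gene_set,
        target=target,
        grouping=grouping,
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(r2),
        adj_r_squared=float(adjusted_r2(r2, n, 1)),
        p_value=float(res.pvalue),
        n_obs=n,
    )


def fit_all_biomarkers(
    medians_by_grouping: dict[str, pd.DataFrame],
    targets: pd.DataFrame,
) -> list[BiomarkerModel]:
    """Fit every (gene set x grouping x target) candidate model.

    ``medians_by_grouping`` maps grouping -> (cell line x gene set) activity
    medians; ``targets`` is a (cell line x {"r", "K"}) table of fitted growth
    parameters.
    """
    models = []
    for grouping, medians in medians_by_grouping.items():
        for target in TARGETS:
            if target not in targets.columns:
                continue
            for gene_set in medians.columns:
                models.append(
                    fit_biomarker(
                        medians[gene_set], targets[target],
                        gene_set=gene_set, target=target, grouping=grouping,
                    )
                )
    return models


def rank_pathways(models: list[BiomarkerModel], top_n: int = 5) -> list[BiomarkerModel]:
    """Rank models of one target by descending adjusted R^2; ties break by
    smaller p-value, then by gene-set name.  Degenerate models are excluded."""
    targets = {m.target for m in models}
    if len(targets) > 1:
        raise InvalidParameterError(f"models mix target parameters: {sorted(targets)}")
    ok = [m for m in models if not m.degenerate and np.isfinite(m.adj_r_squared)]
    ranked = sorted(ok, key=lambda m: (-m.adj_r_squared, m.p_value, m.gene_set, m.grouping))
    return ranked[:top_n]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def validate_biomarkers(
    top_models: list[BiomarkerModel],
    medians_by_grouping: dict[str, pd.DataFrame],
    targets: pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> list[BiomarkerModel]:
    """Refit top-ranked candidate models on the full cell-line cohort.

    Each returned model carries a BH-adjusted p-value (``fdr_q``, family =
    all tested models sharing the same target parameter) and a ``confirmed``
    flag (``fdr_q < fdr_alpha``).  Models whose activity medians are missing
    are skipped with a warning.
    """
    refits: list[BiomarkerModel] = []
    for m in top_models:
        medians = medians_by_grouping.get(m.grouping)
        if medians is None or m.gene_set not in medians.columns:
            warnings.warn(
                f"no activity medians for {m.gene_set}/{m.grouping}; model skipped",
                stacklevel=2,
            )
            continue
        refits.append(
            fit_biomarker(
                medians[m.gene_set], targets[m.target],
                gene_set=m.gene_set, target=m.target, grouping=m.grouping,
            )
        )
    for target in TARGETS:
        group = [m for m in refits if m.target == target and not m.degenerate]
        if not group:
            continue
        q = bh_fdr([m.p_value for m in group])
        for m, qv in zip(group, q):
            m.fdr_q = float(qv)
            m.confirmed = bool(qv < fdr_alpha)
    return refits


def models_table(models: list[BiomarkerModel]) -> pd.DataFrame:
    """Summary table (one row per model) with Pearson, P and R^2 columns."""
    rows = [
        {
            "gene_set": m.gene_set,
            "target": m.target,
            "grouping": m.grouping,
            "slope": m.slope,
            "intercept": m.intercept,
            "Pearson": m.pearson_r,
            "P": m.fdr_q if m.fdr_q is not None else m.p_value,
            "R2": m.adj_r_squared,
            "n": m.n_obs,
            "degenerate": m.degenerate,
            "confirmed": m.confirmed,
        }
        for m in models
    ]
    return pd.DataFrame(rows)
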