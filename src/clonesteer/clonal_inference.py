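"""Per-clone growth-parameter prediction and r/K trade-off detection.

Validated biomarker models map each sequenced cell's pathway activity to a
predicted growth rate and carrying capacity.  Cells are grouped by clone
membership, and for every unordered clone pair (x, y) within a cell line two
two-sided Student's t-tests compare the per-cell predictions of r and of K.
For pairs significant in both (p <= alpha, default 0.1), the mean ratios

    tau_r = mean(r_x) / mean(r_y),   tau_K = mean(K_x) / mean(K_y)

are computed, and the pair is flagged as a potential r/K trade-off when the
ratios point in opposite directions:

    (tau_r < 1 and tau_K > 1)  or  (tau_r > 1 and tau_K < 1).

A trade-off means density conditions decide the winner: the r-advantaged
clone outgrows its partner in sparse culture, the K-advantaged one near
confluence.  No multiple-testing correction is applied across clone pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .biomarker_models import BiomarkerModel
from .errors import InvalidParameterError


@dataclass
class ClonePrediction:
    """Per-cell predicted growth parameters for one clone."""

    clone_id: str
    cell_line: str
    r_cells: np.ndarray
    k_cells: np.ndarray

    def __post_init__(self):
        self.r_cells = np.atleast_1d(np.asarray(self.r_cells, dtype=float))
        self.k_cells = np.atleast_1d(np.asarray(self.k_cells, dtype=float))
        if len(self.r_cells) == 0 and len(self.k_cells) == 0:
            raise InvalidParameterError("clone prediction needs >= 1 cell")
        if not (np.all(np.isfinite(self.r_cells)) and np.all(np.isfinite(self.k_cells))):
            raise InvalidParameterError("predictions must be finite")

    @property
    def r_mean(self) -> float:
        return float(self.r_cells.mean())

    @property
    def k_mean(self) -> float:
        return float(self.k_cells.mean())


@dataclass
class TradeoffResult:
    """Outcome of the paired r/K comparison for one clone pair."""

    clone_x: str
    clone_y: str
    p_r: float
    p_k: float
    tau_r: float
    tau_k: float
    tradeoff: bool


def predict_cell_params(model: BiomarkerModel, activity) -> np.ndarray:
    """Predict delta = a * p + c for per-cell activity scores ``p``."""
    return np.asarray(model.predict(activity), dtype=float)


def build_clone_predictions(
    model_r: BiomarkerModel,
    model_k: BiomarkerModel,
    activity: pd.DataFrame,
    annotations: pd.DataFrame,
    min_cells: int = 2,
) -> dict[str, list[ClonePrediction]]:
    """Predict r and K for every sequenced cell and group by clone.

    Only cells in the phase grouping of each biomarker are used for that
    parameter (a model trained on G2M medians predicts from G2M cells);
    grouping "all" uses every cell.  Clones with fewer than ``min_cells``
    usable cells for either parameter are excluded with a warning.
    """
    ann = annotations.set_index("cell_id") if "cell_id" in annotations.columns else annotations
    ann = ann.loc[ann.index.intersection(activity.index)]
    out: dict[str, list[ClonePrediction]] = {}
    for (line, clone), cells in ann.groupby(["cell_line", "clone_id"], observed=True):
        preds = {}
        for param, model in (("r", model_r), ("K", model_k)):
            sub = cells if model.grouping == "all" else cells[cells["phase"] == model.grouping]
            ids = sub.index
            preds[param] = predict_cell_params(model, activity.loc[ids, model.gene_set])
        if min(len(preds["r"]), len(preds["K"])) < min_cells:
            warnings.warn(
                f"clone {clone} of {line} has < {min_cells} usable cells; excluded",
                stacklevel=2,
            )
            continue
        out.setdefault(str(line), []).append(
            ClonePrediction(str(clone), str(line), preds["r"], preds["K"])
        )
    return out


def _safe_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ttest_ind(a, b, equal_var=equal_var).pvalue
    return 1.0 if np.isnan(p) else float(p)


def pairwise_tradeoff_test(
    pred_x: ClonePrediction,
    pred_y: ClonePrediction,
    alpha: float = 0.1,
    equal_var: bool = True,
) -> TradeoffResult:
    """Test one clone pair for an r/K trade-off.

    Classic equal-variance two-sample Student's t-tests (two-sided) on the
    per-cell predicted r and K; a trade-off requires both p-values <= alpha
    and opposing mean-ratio directions.  Each clone needs >= 2 cells for both
    parameters.
    """
    for pred in (pred_x, pred_y):
        if min(len(pred.r_cells), len(pred.k_cells)) < 2:
            raise InvalidParameterError(
                f"clone {pred.clone_id} has < 2 cells; pair cannot be tested"
            )
    p_r = _safe_p(pred_x.r_cells, pred_y.r_cells, equal_var)
    p_k = _safe_p(pred_x.k_cells, pred_y.k_cells, equal_var)
    tau_r = pred_x.r_mean / pred_y.r_mean if pred_y.r_mean != 0 else np.inf
    tau_k = pred_x.k_mean / pred_y.k_mean if pred_y.k_mean != 0 else np.inf
    opposing = (tau_r < 1 and tau_k > 1) or (tau_r > 1 and tau_k < 1)
    return TradeoffResult(
        clone_x=pred_x.clone_id,
        clone_y=pred_y.clone_id,
        p_r=p_r,
        p_k=p_k,
        tau_r=float(tau_r),
        tau_k=float(tau_k),
        tradeoff=bool(p_r <= alpha and p_k <= alpha and opposing),
    )


def scan_cell_line(
    predictions: list[ClonePrediction],
    alpha: float = 0.1,
    equal_var: bool = True,
) -> list[TradeoffResult]:
    """Test every unordered clone pair of one cell line exactly once."""
    if len(predictions) < 2:
        raise InvalidParameterError("need >= 2 clones to scan for trade-offs")
    results = []
    skipped = [p.clone_id for p in predictions if min(len(p.r_cells), len(p.k_cells)) < 2]
    if skipped:
        warnings.warn(f"clones with < 2 cells skipped: {skipped}", stacklevel=2)
    usable = [p for p in predictions if p.clone_id not in skipped]
    for px, py in itertools.combinations(usable, 2):
        results.append(pairwise_tradeoff_test(px, py, alpha=alpha, equal_var=equal_var))
    return results


def tradeoffs_table(results: list[TradeoffResult], cell_line: str = "") -> pd.DataFrame:
    rows = [
        {
            "cell_line": cell_line,
            "clone_x": t.clone_x,
            "clone_y": t.clone_y,
            "p_r": t.p_r,
            "p_K": t.p_k,
            "tau_r": t.tau_r,
            "tau_K": t.tau_k,
            "tradeoff": t.tradeoff,
        }
        for t in results
    ]
    return pd.DataFrame(rows)
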