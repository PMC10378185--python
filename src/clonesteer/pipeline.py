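"""End-to-end orchestration: fit -> score -> biomarkers -> trade-offs -> steering.

The pipeline mirrors the analysis workflow for a heterogeneous cell-line
cohort:

1. fit the chosen growth model to every cell line's count curve,
2. filter cells and score gene-set activity per cell,
3. summarize activity as per-line medians within each cell-cycle grouping,
4. train candidate linear biomarkers of r and K on the training lines, rank
   by adjusted R^2, validate the top candidates on the full cohort with
   BH-FDR control,
5. predict per-cell r and K from the chosen biomarkers, group by clone, and
   scan every cell line for r/K trade-offs,
6. for the first flagged pair, simulate serial passaging: a steering heatmap
   over (seeding density, splitting interval) schedules plus frequency
   trajectories for a sparse/long and a dense/short schedule.

Every threshold used is echoed into the summary for provenance, and reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData

from . import io as cio
from .biomarker_models import (
    BiomarkerModel,
    fit_all_biomarkers,
    models_table,
    rank_pathways,
    validate_biomarkers,
)
from .clonal_inference import build_clone_predictions, scan_cell_line, tradeoffs_table
from .errors import InvalidParameterError
from .growth_fitting import fit_growth_model
from .growth_models import DEFAULT_AREA_CM2, CloneSystem
from .passaging_sim import PassageSchedule, crossing_passage, run_passage_series, steering_heatmap
from .pathway_activity import (
    DEFAULT_TIE_SEED,
    GROUPINGS,
    aucell_scores,
    filter_cells,
    median_activity_by_group,
)
from .synthetic_data import SEEDING_DENSITY_RANGE

logger = logging.getLogger("clonesteer")


@dataclass
class AnalysisSettings:
    """Thresholds and knobs of the in-memory analysis (defaults are the
    workflow's standard values)."""

    model: str = "verhulst"
    training_lines: tuple = ()
    min_features: int = 200
    top_fraction: float = 0.05
    tie_seed: int = DEFAULT_TIE_SEED
    groupings: tuple = GROUPINGS
    top_n: int = 5
    fdr_alpha: float = 0.05
    alpha_tradeoff: float = 0.1
    run_steering: bool = True
    n_passages: int = 30
    density_grid: tuple = tuple(np.geomspace(*SEEDING_DENSITY_RANGE, 10))
    interval_grid: tuple = (1, 2, 3, 5, 7, 10)
    area_cm2: float = DEFAULT_AREA_CM2
    sparse_schedule: tuple = (SEEDING_DENSITY_RANGE[0], 7.0)  # (density, interval)
    # dense schedule: density None means "seed at dense_occupancy of the
    # flagged system's capacity surface" (split-to-confluence daily)
    dense_schedule: tuple = (None, 1.0)
    dense_occupancy: float = 0.95

    def __post_init__(self):
        for name, val in (
            ("top_fraction", self.top_fraction),
            ("fdr_alpha", self.fdr_alpha),
            ("alpha_tradeoff", self.alpha_tradeoff),
        ):
            if not 0 < val <= 1:
                raise InvalidParameterError(f"{name} must be in (0, 1], got {val}")
        if self.min_features < 0:
            raise InvalidParameterError("min_features must be >= 0")


def _choose_model(validated: list[BiomarkerModel], target: str) -> BiomarkerModel | None:
    cands = [m for m in validated if m.target == target and not m.degenerate]
    if not cands:
        return None
    confirmed = [m for m in cands if m.confirmed]
    pool = confirmed if confirmed else cands
    return max(pool, key=lambda m: m.adj_r_squared)


def _model_dict(m: BiomarkerModel | None) -> dict | None:
    return None if m is None else dataclasses.asdict(m)


def run_analysis(
    curves: dict,
    adata: AnnData,
    annotations: pd.DataFrame,
    gene_sets,
    settings: AnalysisSettings | None = None,
) -> dict:
    """Run the full analysis in memory and return a report dictionary.

    ``curves`` maps cell-line name -> GrowthCurve; ``adata`` is the joint
    cells x genes expression matrix; ``annotations`` carries cell_id /
    cell_line / clone_id / phase; ``gene_sets`` the candidate pathways.
    """
    s = settings or AnalysisSettings()
    lines = sorted(curves)
    training = tuple(s.training_lines) or tuple(lines[: max(3, len(lines) - 3)])
    validation = tuple(l for l in lines if l not in training)

    # 1. growth-model fits per cell line
    fits = {name: fit_growth_model(curves[name], s.model) for name in lines}
    bad = [n for n, f in fits.items() if not f.converged]
    if bad:
        raise InvalidParameterError(f"growth fit failed for cell line(s) {bad}")
    targets = pd.DataFrame(
        {
            "r": {n: f.params.r for n, f in fits.items()},
            "K": {n: f.params.K for n, f in fits.items()},
        }
    )

    # 2-3. score cells, summarize per grouping
    kept = filter_cells(adata, s.min_features)
    activity = aucell_scores(kept, gene_sets, s.top_fraction, s.tie_seed)
    medians_all = {
        g: median_activity_by_group(activity, annotations, g) for g in s.groupings
    }
    medians_train = {g: df.loc[df.index.intersection(training)] for g, df in medians_all.items()}

    # 4. train on the training lines, validate on the full cohort;
    # candidates are ranked within each (target, grouping) family
    candidates = fit_all_biomarkers(medians_train, targets.loc[list(training)])
    top = {
        t: [
            m
            for g in s.groupings
            for m in rank_pathways(
                [c for c in candidates if c.target == t and c.grouping == g], s.top_n
            )
        ]
        for t in ("r", "K")
    }
    validated = validate_biomarkers(top["r"] + top["K"], medians_all, targets, s.fdr_alpha)
    model_r = _choose_model(validated, "r")
    model_k = _choose_model(validated, "K")

    report: dict = {
        "settings": {
            "model": s.model,
            "training_lines": list(training),
            "validation_lines": list(validation),
            "min_features": s.min_features,
            "top_fraction": s.top_fraction,
            "tie_seed": s.tie_seed,
            "top_n": s.top_n,
            "fdr_alpha": s.fdr_alpha,
            "alpha_tradeoff": s.alpha_tradeoff,
            "n_passages": s.n_passages,
            "area_cm2": s.area_cm2,
        },
        "growth_fits": {
            n: {
                "r": f.params.r,
                "K": f.params.K,
                "n0": f.params.n0,
                "adj_r_squared": f.adj_r_squared,
                "aic": f.aic,
            }
            for n, f in fits.items()
        },
        "n_cells_kept": int(kept.n_obs),
        "top_candidates": {
            t: [f"{m.gene_set}/{m.grouping}" for m in top[t]] for t in ("r", "K")
        },
        "confirmed_biomarkers": [
            f"{m.gene_set}/{m.grouping}/{m.target}" for m in validated if m.confirmed
        ],
        "chosen_model_r": _model_dict(model_r),
        "chosen_model_k": _model_dict(model_k),
    }
    report["_tables"] = {"validated": models_table(validated)}

    if model_r is None or model_k is None:
        logger.warning("no usable biomarker for r and/or K; stopping before trade-offs")
        report["tradeoffs"] = {}
        return report

    # 5. per-clone predictions and trade-off scan
    clone_preds = build_clone_predictions(model_r, model_k, activity, annotations)
    tradeoffs = {}
    clone_pred_summary = {}
    for line, preds in sorted(clone_preds.items()):
        clone_pred_summary[line] = {
            p.clone_id: {"r_mean": p.r_mean, "K_mean": p.k_mean, "n_cells": len(p.r_cells)}
            for p in preds
        }
        if len(preds) >= 2:
            tradeoffs[line] = scan_cell_line(preds, alpha=s.alpha_tradeoff)
    report["clone_predictions"] = clone_pred_summary
    report["tradeoffs"] = {
        line: [dataclasses.asdict(t) for t in res] for line, res in tradeoffs.items()
    }
    flagged = [
        (line, t)
        for line, res in sorted(tradeoffs.items())
        for t in res
        if t.tradeoff
    ]
    report["flagged_pairs"] = [
        {"cell_line": line, "clone_x": t.clone_x, "clone_y": t.clone_y}
        for line, t in flagged
    ]
    report["_tables"]["tradeoffs"] = pd.concat(
        [tradeoffs_table(res, line) for line, res in sorted(tradeoffs.items())],
        ignore_index=True,
    ) if tradeoffs else pd.DataFrame()

    # 6. steering simulation for the first flagged pair
    if s.run_steering and flagged:
        line, t = flagged[0]
        preds = {p.clone_id: p for p in clone_preds[line]}
        system = CloneSystem(
            clone_ids=[p.clone_id for p in clone_preds[line]],
            r=[p.r_mean for p in clone_preds[line]],
            K=[p.k_mean for p in clone_preds[line]],
        )
        # designate the pair's roles from the predicted means
        r_clone = t.clone_x if preds[t.clone_x].r_mean > preds[t.clone_y].r_mean else t.clone_y
        k_clone = t.clone_y if r_clone == t.clone_x else t.clone_x
        # observed clonal composition seeds the first passage
        counts = np.array([len(p.r_cells) for p in clone_preds[line]], dtype=float)
        freqs = counts / counts.sum()
        heatmap = steering_heatmap(
            system,
            s.density_grid,
            s.interval_grid,
            r_clone=r_clone,
            k_clone=k_clone,
            n_passages=s.n_passages,
            initial_frequencies=freqs,
            area_cm2=s.area_cm2,
        )
        trajectories = {}
        crossings = {}
        for label, (density, interval) in (
            ("sparse_long", s.sparse_schedule),
            ("dense_short", s.dense_schedule),
        ):
            if density is None:
                density = s.dense_occupancy / np.sum(freqs / system.K) / s.area_cm2
            schedule = PassageSchedule(
                seeding_density=density,
                interval_days=interval,
                n_passages=s.n_passages,
                area_cm2=s.area_cm2,
            )
            outcome = run_passage_series(system, schedule, freqs)
            trajectories[label] = outcome
            cp = crossing_passage(outcome, r_clone, k_clone)
            crossings[label] = None if cp is None else int(cp)
        report["steering"] = {
            "cell_line": line,
            "r_clone": r_clone,
            "k_clone": k_clone,
            "metric_min": float(np.nanmin(heatmap.to_numpy())),
            "metric_max": float(np.nanmax(heatmap.to_numpy())),
            "crossing_passage": crossings,
        }
        report["_tables"]["heatmap"] = heatmap
        report["_tables"]["trajectories"] = {
            k: v.to_frame() for k, v in trajectories.items()
        }
    return report


# --------------------------------------------------------------- file pipeline

@dataclass
class PipelineConfig:
    """File-level pipeline configuration (YAML-loadable)."""

    counts: str
    expression: str
    annotations: str
    gene_sets: str
    out_dir: str
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        settings = AnalysisSettings(**raw.pop("settings", {}))
        return cls(settings=settings, **raw)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the file-level pipeline and write per-stage artifacts.

    Writes fits + summary JSON, activity / biomarker / trade-off CSVs and,
    when a trade-off is flagged, the steering heatmap and frequency
    trajectories.  Raises on invalid inputs; partial artifacts are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("reading inputs")
    curves = cio.read_growth_curves(config.counts)
    adata = cio.read_expression(config.expression)
    annotations = cio.read_annotations(config.annotations)
    gene_sets = cio.read_gmt(config.gene_sets)
    shared = set(annotations["cell_id"]) & set(adata.obs_names)
    if not shared:
        raise InvalidParameterError(
            f"{config.annotations}: no cell IDs shared with the expression matrix"
        )

    report = run_analysis(curves, adata, annotations, gene_sets, config.settings)
    tables = report.pop("_tables", {})

    tables.get("validated", pd.DataFrame()).to_csv(out / "biomarkers.csv", index=False)
    if "tradeoffs" in tables:
        tables["tradeoffs"].to_csv(out / "tradeoffs.csv", index=False)
    if "heatmap" in tables:
        tables["heatmap"].to_csv(out / "steering_heatmap.csv")
    for label, df in tables.get("trajectories", {}).items():
        df.to_csv(out / f"trajectory_{label}.csv")
    if config.make_plots and "heatmap" in tables:
        from .plots import plot_steering_heatmap

        plot_steering_heatmap(tables["heatmap"]).figure.savefig(
            out / "steering_heatmap.png", dpi=150
        )

    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    logger.info("pipeline complete: %s", out / "summary.json")
    return report
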