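"""Readers and writers for the pipeline's file formats.

Formats: cell-count CSV (``time_days, count, population_id``), expression as
MatrixMarket MTX (genes x cells, with ``genes.tsv`` / ``barcodes.tsv``
sidecars) or dense CSV (genes x cells), annotations TSV
(``cell_id, cell_line, clone_id, phase``), gene sets as GMT, clone systems
and pipeline configuration as YAML.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml
from anndata import AnnData

from .errors import InvalidParameterError
from .growth_models import CloneSystem, GrowthCurve
from .pathway_activity import PHASES, GeneSet

ANNOTATION_COLUMNS = ("cell_id", "cell_line", "clone_id", "phase")


# ---------------------------------------------------------------- growth curves

def write_growth_curves(curves, path) -> None:
    """Write one or more GrowthCurves as a long CSV."""
    if isinstance(curves, GrowthCurve):
        curves = [curves]
    if isinstance(curves, dict):
        curves = list(curves.values())
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(path, index=False)


def read_growth_curves(path) -> dict[str, GrowthCurve]:
    """Read a counts CSV into one GrowthCurve per population_id."""
    df = pd.read_csv(path)
    required = {"time_days", "count", "population_id"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"{path}: counts CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = {}
    for pid, sub in df.groupby("population_id", sort=False):
        sub = sub.sort_values("time_days")
        out[str(pid)] = GrowthCurve(
            times=sub["time_days"].to_numpy(),
            counts=sub["count"].to_numpy(),
            population_id=str(pid),
        )
    return out


# ------------------------------------------------------------------- expression

def write_expression_mtx(adata: AnnData, out_dir) -> None:
    """Write genes x cells MTX with genes.tsv / barcodes.tsv sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not scipy.sparse.issparse(X):
        X = scipy.sparse.csr_matrix(np.asarray(X))
    scipy.io.mmwrite(os.fspath(out_dir / "matrix.mtx"), X.T)  # genes x cells
    pd.Series(adata.var_names).to_csv(out_dir / "genes.tsv", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out_dir / "barcodes.tsv", index=False, header=False)


def read_expression_mtx(in_dir) -> AnnData:
    """Read a genes x cells MTX directory into a cells x genes AnnData."""
    in_dir = Path(in_dir)
    mat = scipy.io.mmread(os.fspath(in_dir / "matrix.mtx")).tocsr().T
    genes = pd.read_csv(in_dir / "genes.tsv", header=None)[0].astype(str)
    cells = pd.read_csv(in_dir / "barcodes.tsv", header=None)[0].astype(str)
    return AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )


def read_expression_csv(path) -> AnnData:
    """Read a dense genes x cells CSV (gene IDs in the first column)."""
    df = pd.read_csv(path, index_col=0)
    return AnnData(
        X=df.to_numpy(dtype=float).T,
        obs=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(df.index.astype(str), name="gene_id")),
    )


def read_expression(path) -> AnnData:
    """Dispatch on path type: a directory is MTX + sidecars, a file dense CSV."""
    path = Path(path)
    return read_expression_mtx(path) if path.is_dir() else read_expression_csv(path)


# ------------------------------------------------------------------ annotations

def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read and validate the cell annotation TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    if len(df) == 0:
        raise InvalidParameterError(f"{path}: annotation file is empty")
    bad = set(df["phase"]) - set(PHASES)
    if bad:
        raise InvalidParameterError(f"{path}: unknown cell-cycle phases {sorted(bad)}")
    return df.astype({c: str for c in ("cell_id", "cell_line", "clone_id", "phase")})


# -------------------------------------------------------------------- gene sets

def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets.append(GeneSet(fields[0], tuple(g for g in fields[2:] if g)))
    if not sets:
        raise InvalidParameterError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


# ----------------------------------------------------------------- clone system

def read_clone_system(path) -> CloneSystem:
    """Read a clone system from YAML: v, and a clones list of
    {id, r, K, n0}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    clones = cfg.get("clones", [])
    if not clones:
        raise InvalidParameterError(f"{path}: no clones defined")
    return CloneSystem(
        clone_ids=[c["id"] for c in clones],
        r=[c["r"] for c in clones],
        K=[c["K"] for c in clones],
        v=float(cfg.get("v", 1.0)),
        state=[c.get("n0", 0.0) for c in clones],
    )


def write_clone_system(system: CloneSystem, path) -> None:
    cfg = {
        "v": float(system.v),
        "clones": [
            {
                "id": cid,
                "r": float(r),
                "K": float(K),
                **({"n0": float(n)} if system.state is not None else {}),
            }
            for cid, r, K, n in zip(
                system.clone_ids,
                system.r,
                system.K,
                system.state if system.state is not None else np.zeros(system.n_clones),
            )
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
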