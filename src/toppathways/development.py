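"""Marker-based developmental scores and cell-type proportion kinetics.

A gene-set module score is the per-cell mean of z-scored log1p(CP10K)
expression over the set's genes (z-scoring per gene across all cells;
zero-variance genes contribute 0). The developmental score of a cell is its
maturation-set score minus its progenitor-set score, so positive values mark
maturing cells; cluster means summarize the maturation state of each cell
type. Proportion tables count cell types within (compartment, subset, stage)
strata, and first-appearance detection scans the ordered stages for the
earliest one where a cell type exceeds a presence threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)


def module_score(ds: ExpressionDataset, gene_set: list[str]) -> pd.Series:
    """Mean z-scored log1p(CP10K) expression over ``gene_set``, per cell.

    Genes absent from the dataset are dropped with a warning; an empty
    intersection raises. Genes constant across all cells contribute zero.
    """
    if ds.normalized is None:
        raise ValidationError("normalized layer missing; run normalize_cp10k first")
    present = [g for g in dict.fromkeys(gene_set) if g in ds.gene_ids]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValidationError(f"no gene of the set is in the dataset; missing: {missing}")
    if missing:
        logger.warning("module score: %d genes absent from dataset: %s", len(missing), missing)
    rows = ds.gene_ids.get_indexer(present)
    X = np.log1p(np.asarray(ds.normalized[rows].todense()))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mu) / sd
    Z[~np.isfinite(Z)] = 0.0  # zero-variance genes contribute 0
    return pd.Series(Z.mean(axis=0), index=ds.cells["cell_id"].to_numpy(), name="module_score")


def developmental_score(
    ds: ExpressionDataset,
    maturation_set: list[str],
    progenitor_set: list[str],
) -> pd.DataFrame:
    """Per-cell maturation minus progenitor module score.

    Returns a DataFrame indexed by cell_id with columns maturation_score,
    progenitor_score, dev_score and cluster; per-cluster means are available
    via ``cluster_dev_scores``.
    """
    mat = module_score(ds, maturation_set)
    prog = module_score(ds, progenitor_set)
    return pd.DataFrame(
        {
            "maturation_score": mat,
            "progenitor_score": prog,
            "dev_score": mat - prog,
            "cluster": ds.cells.set_index("cell_id")["cluster"],
        }
    )


def cluster_dev_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster means of the developmental score table (lexicographic order)."""
    return (
        table.groupby("cluster", sort=True)[
            ["maturation_score", "progenitor_score", "dev_score"]
        ].mean()
    )


def celltype_proportions(
    ds: ExpressionDataset, compartment_map: dict[str, str]
) -> pd.DataFrame:
    """Cell-type counts and fractions within (compartment, subset, stage) strata.

    Every cluster must be assigned a compartment; fractions within each
    stratum sum to 1. Rows are ordered by (compartment, subset, stage-order
    position, cell type); empty strata simply do not appear.
    """
    unmapped = set(ds.cells["cluster"]) - set(compartment_map)
    if unmapped:
        raise ValidationError(f"clusters missing from compartment_map: {sorted(unmapped)}")
    cells = ds.cells.copy()
    cells["compartment"] = cells["cluster"].map(compartment_map)
    counts = (
        cells.groupby(["compartment", "subset", "stage", "cluster"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"cluster": "cell_type"})
    )
    totals = counts.groupby(["compartment", "subset", "stage"])["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    counts["stage"] = pd.Categorical(counts["stage"], categories=ds.stage_order, ordered=True)
    counts = counts.sort_values(
        ["compartment", "subset", "stage", "cell_type"]
    ).reset_index(drop=True)
    return counts


def first_appearance(
    proportions: pd.DataFrame,
    cell_type: str,
    min_fraction: float = 0.01,
    stage_order: list[str] | None = None,
) -> dict[str, str]:
    """Earliest stage per subset where ``cell_type`` reaches ``min_fraction``.

    Stages are compared by position in the ordered stage list (taken from the
    proportion table's categorical stage column unless given explicitly);
    subsets where the threshold is never reached map to "absent".
    """
    known = set(proportions["cell_type"])
    if cell_type not in known:
        raise ValidationError(f"unknown cell type {cell_type!r}; known: {sorted(known)}")
    if stage_order is None:
        if not isinstance(proportions["stage"].dtype, pd.CategoricalDtype):
            raise ValidationError("stage column is not ordered; pass stage_order")
        stage_order = list(proportions["stage"].cat.categories)
    rows = proportions[proportions["cell_type"] == cell_type]
    out: dict[str, str] = {}
    for subset in sorted(proportions["subset"].unique()):
        sub = rows[rows["subset"] == subset]
        by_stage = sub.groupby("stage", observed=True)["fraction"].max()
        found = "absent"
        for stage in stage_order:
            if stage in by_stage.index and by_stage[stage] >= min_fraction:
                found = stage
                break
        out[subset] = found
    return out


def load_marker_sets(path) -> dict[str, list[str]]:
    """Read a TSV of (set_name, gene) rows into named gene lists."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"set_name", "gene"} - set(df.columns):
        raise ValidationError(f"marker file {path} needs columns set_name, gene")
    return {name: grp["gene"].tolist() for name, grp in df.groupby("set_name", sort=True)}


def load_compartment_map(path) -> dict[str, str]:
    """Read a TSV of (cluster, compartment) rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"cluster", "compartment"} - set(df.columns):
        raise ValidationError(f"compartment file {path} needs columns cluster, compartment")
    return dict(zip(df["cluster"], df["compartment"]))
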