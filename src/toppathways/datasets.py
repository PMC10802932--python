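"""Expression containers, IO, QC filtering, normalization and cluster profiles.

The pipeline consumes a gene x cell sparse UMI count matrix with per-cell
metadata (cluster, developmental stage, subset such as incisor/molar, and the
cell's UMI total). Counts live in Matrix Market coordinate format next to two
TSV annotation tables; this module round-trips that layout exactly.

Quality control follows the usual band-pass on library size — cells with a UMI
total outside [min_umi, max_umi] are discarded (bounds inclusive) — followed by
removal of mitochondrial genes by identifier prefix. Normalization is counts
per 10,000 (CP10K): each cell's counts divided by its UMI total times 1e4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import EmptyDatasetError, LoadError, ValidationError

logger = logging.getLogger(__name__)

CELL_COLUMNS = ["cell_id", "cluster", "stage", "subset", "umi"]


@dataclass
class QCParams:
    """Cell- and gene-level quality-control thresholds.

    min_umi/max_umi bound the per-cell UMI total (inclusive); mito_prefix
    marks mitochondrial genes for removal (matched case-insensitively).
    """

    min_umi: int = 100
    max_umi: int = 1500
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0 <= self.min_umi <= self.max_umi):
            raise ValidationError(
                f"require 0 <= min_umi <= max_umi, got [{self.min_umi}, {self.max_umi}]"
            )


@dataclass
class ExpressionDataset:
    """Sparse gene x cell counts plus per-cell metadata.

    counts      gene x cell sparse non-negative integer matrix (CSR)
    gene_ids    ordered unique gene identifiers (rows of counts)
    cells       DataFrame with columns cell_id, cluster, stage, subset, umi
    stage_order ordered list of valid stage labels (earliest first)
    normalized  optional CP10K layer, same shape as counts
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cells: pd.DataFrame
    stage_order: list[str]
    normalized: sp.csr_matrix | None = None

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.cells)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cells)} cells"
            )
        if self.gene_ids.has_duplicates:
            dups = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:10]}")
        if self.cells["cell_id"].duplicated().any():
            dups = self.cells.loc[self.cells["cell_id"].duplicated(), "cell_id"]
            raise ValidationError(f"duplicate cell ids: {dups.head(10).tolist()}")
        bad_stages = set(self.cells["stage"]) - set(self.stage_order)
        if bad_stages:
            raise ValidationError(
                f"stage labels {sorted(bad_stages)} absent from stage_order "
                f"{self.stage_order}"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        colsums = np.asarray(self.counts.sum(axis=0)).ravel()
        if not np.array_equal(colsums, self.cells["umi"].to_numpy()):
            n_bad = int((colsums != self.cells["umi"].to_numpy()).sum())
            logger.warning(
                "umi column disagrees with counts column sums for %d cells", n_bad
            )
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValidationError("normalized layer shape differs from counts")

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            counts=self.counts.copy(),
            gene_ids=self.gene_ids.copy(),
            cells=self.cells.copy(),
            stage_order=list(self.stage_order),
            normalized=None if self.normalized is None else self.normalized.copy(),
        )

    def to_anndata(self):
        """Bridge to an AnnData (cells x genes) for interop with scanpy et al."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cells.set_index("cell_id"),
            var=pd.DataFrame(index=self.gene_ids),
        )
        if self.normalized is not None:
            adata.layers["cp10k"] = self.normalized.T.tocsr()
        adata.uns["stage_order"] = list(self.stage_order)
        return adata


@dataclass
class ClusterProfile:
    """Per-cluster expression summary.

    mean_expr  gene x cluster mean CP10K expression (DataFrame)
    expr_frac  gene x cluster fraction of cells with count > 0 (DataFrame)
    n_cells    cells per cluster (Series)

    Cluster order is lexicographic for determinism.
    """

    clusters: list[str]
    mean_expr: pd.DataFrame
    expr_frac: pd.DataFrame
    n_cells: pd.Series


def load_expression(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    stage_order: list[str],
) -> ExpressionDataset:
    """Read a Matrix Market counts matrix (genes as rows) with its TSV tables.

    genes.tsv holds one gene id per line (extra columns ignored); cells.tsv is
    tab-separated with header cell_id, cluster, stage, subset and optionally
    umi. The umi column is recomputed from column sums when absent, and checked
    (warning on mismatch) when present.
    """
    matrix_path, genes_path, cells_path = map(Path, (matrix_path, genes_path, cells_path))
    try:
        counts = sp.csr_matrix(mmread(str(matrix_path)))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise LoadError(f"cannot read matrix file {matrix_path}: {exc}") from exc
    genes = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    gene_ids = pd.Index(genes.iloc[:, 0], name="gene_id")
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str})
    missing_cols = {"cell_id", "cluster", "stage", "subset"} - set(cells.columns)
    if missing_cols:
        raise LoadError(f"cells table {cells_path} lacks columns {sorted(missing_cols)}")

    if counts.shape[0] != len(gene_ids):
        raise LoadError(
            f"gene table {genes_path} has {len(gene_ids)} rows but matrix "
            f"{matrix_path} has {counts.shape[0]} rows"
        )
    if counts.shape[1] != len(cells):
        raise LoadError(
            f"cells table {cells_path} has {len(cells)} rows but matrix "
            f"{matrix_path} has {counts.shape[1]} columns"
        )
    colsums = np.asarray(counts.sum(axis=0)).ravel().astype(np.int64)
    if "umi" not in cells.columns:
        cells = cells.assign(umi=colsums)
    cells["umi"] = cells["umi"].astype(np.int64)
    ds = ExpressionDataset(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cells=cells.reset_index(drop=True),
        stage_order=list(stage_order),
    )
    ds.validate()
    return ds


def write_expression(ds: ExpressionDataset, outdir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx, genes.tsv and cells.tsv; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "cells": outdir / "cells.tsv",
    }
    mmwrite(str(paths["matrix"]), ds.counts.tocoo(), field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in ds.gene_ids))
    ds.cells.to_csv(paths["cells"], sep="\t", index=False, columns=CELL_COLUMNS)
    return paths


def qc_filter(ds: ExpressionDataset, params: QCParams | None = None) -> ExpressionDataset:
    """Band-pass cells on UMI total, then drop mitochondrial genes.

    Cells with min_umi <= umi <= max_umi (inclusive) are kept, judged on the
    UMI totals as stored *before* gene removal. Genes whose id starts with
    mito_prefix (case-insensitive) are then dropped and the umi column is
    recomputed so that downstream CP10K normalization sums to exactly 1e4.
    Returns a new dataset; the input is untouched. Idempotent.
    """
    params = params or QCParams()
    umi = ds.cells["umi"].to_numpy()
    cell_keep = (umi >= params.min_umi) & (umi <= params.max_umi)
    if not cell_keep.any():
        raise EmptyDatasetError(
            f"UMI filter [{params.min_umi}, {params.max_umi}] removed all "
            f"{ds.n_cells} cells"
        )
    prefix = params.mito_prefix.upper()
    gene_keep = ~ds.gene_ids.str.upper().str.startswith(prefix)
    n_mito = int((~gene_keep).sum())
    if n_mito:
        logger.info("removing %d mitochondrial genes (prefix %r)", n_mito, params.mito_prefix)
    counts = ds.counts[np.asarray(gene_keep)][:, cell_keep].tocsr()
    cells = ds.cells.loc[cell_keep].reset_index(drop=True).copy()
    cells["umi"] = np.asarray(counts.sum(axis=0)).ravel().astype(np.int64)
    out = ExpressionDataset(
        counts=counts,
        gene_ids=ds.gene_ids[gene_keep],
        cells=cells,
        stage_order=list(ds.stage_order),
    )
    out.validate()
    return out


def normalize_cp10k(ds: ExpressionDataset) -> ExpressionDataset:
    """Attach a CP10K layer: counts / cell UMI total * 10,000.

    Every cell must have umi > 0 (run qc_filter first); the raw counts are
    retained unchanged.
    """
    umi = ds.cells["umi"].to_numpy()
    if (umi <= 0).any():
        n_zero = int((umi <= 0).sum())
        raise ValidationError(
            f"{n_zero} cells have zero UMI; run qc_filter before normalize_cp10k"
        )
    scale = sp.diags(1e4 / umi.astype(np.float64))
    normalized = (ds.counts @ scale).tocsr()
    return replace(ds, normalized=normalized)


def cluster_profile(ds: ExpressionDataset) -> ClusterProfile:
    """Mean CP10K expression and expressed-cell fraction per cluster.

    Requires the normalized layer. Clusters are ordered lexicographically.
    """
    if ds.normalized is None:
        raise ValidationError("normalized layer missing; run normalize_cp10k first")
    labels = ds.cells["cluster"].to_numpy()
    clusters = sorted(pd.unique(labels))
    cols = np.searchsorted(np.array(clusters), labels)
    n_cells = np.bincount(cols, minlength=len(clusters))
    # cells x clusters membership indicator, scaled to average
    member = sp.csr_matrix(
        (1.0 / n_cells[cols], (np.arange(ds.n_cells), cols)),
        shape=(ds.n_cells, len(clusters)),
    )
    mean_expr = np.asarray((ds.normalized @ member).todense())
    expr_frac = np.asarray(((ds.counts > 0) @ member).todense())
    return ClusterProfile(
        clusters=list(clusters),
        mean_expr=pd.DataFrame(mean_expr, index=ds.gene_ids, columns=clusters),
        expr_frac=pd.DataFrame(expr_frac, index=ds.gene_ids, columns=clusters),
        n_cells=pd.Series(n_cells, index=clusters, name="n_cells"),
    )


def aggregate_pathway_heatmap(profile: ClusterProfile, db, pathway: str, role: str) -> pd.Series:
    """Per-cluster sum of mean expression over a pathway's ligands or receptors.

    Each distinct gene of the requested role is counted once; genes absent from
    the dataset contribute zero (logged). Intended for heatmap export.
    """
    if role not in ("ligand", "receptor"):
        raise ValidationError(f"role must be 'ligand' or 'receptor', got {role!r}")
    rows = db.lr_pairs[db.lr_pairs["pathway"] == pathway]
    if rows.empty:
        raise ValidationError(
            f"unknown pathway {pathway!r}; available: {db.pathway_names}"
        )
    genes = sorted(rows[role].unique())
    if not genes:
        raise ValidationError(f"pathway {pathway!r} has no {role} genes in the database")
    present = [g for g in genes if g in profile.mean_expr.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.warning("pathway %s: %s genes absent from dataset: %s", pathway, role, missing)
    if not present:
        return pd.Series(0.0, index=profile.clusters, name=f"{pathway}_{role}")
    vec = profile.mean_expr.loc[present].sum(axis=0)
    vec.name = f"{pathway}_{role}"
    return vec


def write_heatmap_tsv(vector: pd.Series, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a (cluster, value) TSV, optionally with '#'-prefixed provenance lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("cluster\tvalue\n")
        for cluster, value in vector.items():
            fh.write(f"{cluster}\t{value:.10g}\n")


def write_heatmap_png(vector: pd.Series, path: str | Path) -> None:
    """Render the aggregated pathway expression vector as a one-row heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(3, 0.6 * len(vector)), 1.6))
    im = ax.imshow(vector.to_numpy()[None, :], aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(vector)), vector.index, rotation=45, ha="right")
    ax.set_yticks([])
    ax.set_title(str(vector.name))
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
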