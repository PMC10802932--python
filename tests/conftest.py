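import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from toppathways import ClusterProfile, ExpressionDataset, PathwayDatabase


def make_dataset(
    counts: np.ndarray,
    gene_ids: list[str],
    clusters: list[str],
    stages: list[str] | None = None,
    subsets: list[str] | None = None,
    stage_order: list[str] | None = None,
    normalized: np.ndarray | None = None,
) -> ExpressionDataset:
    """Build a small in-memory dataset from dense arrays."""
    counts = np.asarray(counts)
    n_cells = counts.shape[1]
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "cluster": clusters,
            "stage": stages or ["s1"] * n_cells,
            "subset": subsets or ["A"] * n_cells,
            "umi": counts.sum(axis=0).astype(np.int64),
        }
    )
    ds = ExpressionDataset(
        counts=sp.csr_matrix(counts.astype(np.int64)),
        gene_ids=pd.Index(gene_ids, name="gene_id"),
        cells=cells,
        stage_order=stage_order or sorted(set(stages or ["s1"])),
        normalized=None if normalized is None else sp.csr_matrix(np.asarray(normalized, dtype=float)),
    )
    ds.validate()
    return ds


def make_profile(mean_expr: dict, expr_frac: dict | None = None) -> ClusterProfile:
    """Profile from {gene: {cluster: value}} dicts; expr_frac defaults to 1."""
    me = pd.DataFrame(mean_expr).T.sort_index(axis=1)
    ef = pd.DataFrame(expr_frac).T.sort_index(axis=1) if expr_frac else pd.DataFrame(
        1.0, index=me.index, columns=me.columns
    )
    clusters = list(me.columns)
    return ClusterProfile(
        clusters=clusters,
        mean_expr=me,
        expr_frac=ef,
        n_cells=pd.Series(2, index=clusters),
    )


def make_db(lr, rtf=None, tft=None) -> PathwayDatabase:
    db = PathwayDatabase(
        lr_pairs=pd.DataFrame(lr, columns=["ligand", "receptor", "pathway"]),
        receptor_tf=pd.DataFrame(rtf or [], columns=["receptor", "tf"]),
        tf_target=pd.DataFrame(tft or [], columns=["tf", "target"]),
    )
    db.validate()
    return db


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """Six genes x six cells in two clusters, no mito genes."""
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 20, size=(6, 6))
    return make_dataset(
        counts,
        gene_ids=[f"G{i}" for i in range(6)],
        clusters=["A", "A", "A", "B", "B", "B"],
    )


@pytest.fixture
def toy_db() -> PathwayDatabase:
    return make_db(
        lr=[("L1", "R1", "FGF"), ("L2", "R2", "BMP")],
        rtf=[("R1", "TF1"), ("R2", "TF2")],
        tft=[("TF1", "T1"), ("TF2", "T2")],
    )
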