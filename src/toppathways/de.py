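"""Progenitor-vs-mature differential expression with BH-FDR.

Per gene, a two-sided Wilcoxon rank-sum test compares CP10K expression
between the progenitor and mature cell groups. Small groups (both sizes at
or below ``exact_max_n``) use exact enumeration of the rank-sum null over all
group assignments with midranks for ties; larger groups use the tie-corrected
normal approximation (no continuity correction). Fold change is computed on
CP10K cluster means with a pseudocount:

    fold_change = (mean_mature + eps) / (mean_prog + eps)

so ratios stay bounded for lowly expressed genes. Multiple testing uses
Benjamini-Hochberg step-up adjustment, and the downstream DEG filter keeps
genes with fdr < 0.1 and fold change beyond 2x in either direction (strict
inequalities).
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "mean_prog", "mean_mature", "fold_change", "log2_fc", "p_value", "fdr", "direction",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exact_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Exact two-sided rank-sum p by enumerating all group-1 assignments.

    ``ranks`` are the pooled midranks; the observed group 1 occupies the first
    ``n1`` positions. p = P(|W - E[W]| >= |W_obs - E[W]|) under exchangeability.
    """
    n = len(ranks)
    mu = n1 * (n + 1) / 2.0
    d_obs = abs(ranks[:n1].sum() - mu)
    hits = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / comb(n, n1)


def _asymptotic_ranksum_p(X: np.ndarray, n1: int) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum p per gene row."""
    G, n = X.shape
    n2 = n - n1
    ranks = rankdata(X, axis=1)
    W = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    tie_term = np.zeros(G)
    for g in range(G):
        _, counts = np.unique(X[g], return_counts=True)
        tie_term[g] = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(G)
    pos = var > 0
    z = (W[pos] - mu) / np.sqrt(var[pos])
    p[pos] = np.minimum(1.0, 2.0 * norm.sf(np.abs(z)))
    return p


def differential_expression(
    ds: ExpressionDataset,
    progenitor_cluster: str,
    mature_cluster: str,
    epsilon: float = 0.01,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Per-gene rank-sum test between two clusters on CP10K expression.

    Returns a DataFrame indexed by gene with columns mean_prog, mean_mature,
    fold_change, log2_fc, p_value, fdr and direction ('up' when
    mean_mature >= mean_prog). Genes constant across both groups get p = 1.
    """
    if ds.normalized is None:
        raise ValidationError("normalized layer missing; run normalize_cp10k first")
    labels = ds.cells["cluster"].to_numpy()
    for name in (progenitor_cluster, mature_cluster):
        n = int((labels == name).sum())
        if n < 2:
            raise ValidationError(
                f"cluster {name!r} has {n} cells; need at least 2 for the rank-sum test"
            )
    prog_mask = labels == progenitor_cluster
    mat_mask = labels == mature_cluster
    Xp = np.asarray(ds.normalized[:, prog_mask].todense())
    Xm = np.asarray(ds.normalized[:, mat_mask].todense())
    n1, n2 = Xp.shape[1], Xm.shape[1]
    X = np.hstack([Xp, Xm])

    if n1 <= exact_max_n and n2 <= exact_max_n:
        p = np.empty(X.shape[0])
        for g in range(X.shape[0]):
            row = X[g]
            if np.all(row == row[0]):
                p[g] = 1.0
            else:
                p[g] = _exact_ranksum_p(rankdata(row), n1)
    else:
        p = _asymptotic_ranksum_p(X, n1)

    mean_prog = Xp.mean(axis=1)
    mean_mature = Xm.mean(axis=1)
    fold_change = (mean_mature + epsilon) / (mean_prog + epsilon)
    result = pd.DataFrame(
        {
            "mean_prog": mean_prog,
            "mean_mature": mean_mature,
            "fold_change": fold_change,
            "log2_fc": np.log2(fold_change),
            "p_value": p,
            "fdr": bh_adjust(p),
            "direction": np.where(mean_mature >= mean_prog, "up", "down"),
        },
        index=ds.gene_ids,
    )
    return result


def filter_deg(
    result: pd.DataFrame,
    max_fdr: float = 0.1,
    min_fc: float = 2.0,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Apply the DEG filter: fdr < max_fdr and fold change beyond min_fc.

    With ``two_sided`` (default) a gene passes when max(FC, 1/FC) > min_fc, so
    both up- and down-regulated genes are retained; one-sided keeps only
    FC > min_fc. Inequalities are strict. An empty result is allowed (warned).
    """
    fc = result["fold_change"]
    extreme = np.maximum(fc, 1.0 / fc) if two_sided else fc
    keep = (result["fdr"] < max_fdr) & (extreme > min_fc)
    out = result.loc[keep].copy()
    if out.empty:
        logger.warning(
            "DEG filter (fdr<%.3g, fc>%.3g) kept no genes", max_fdr, min_fc
        )
    return out


def write_deg_tsv(
    result: pd.DataFrame,
    kept: pd.DataFrame,
    path,
    header_lines: list[str] | None = None,
) -> None:
    """Export the full differential result with a boolean 'kept' flag."""
    table = result.copy()
    table["kept"] = table.index.isin(kept.index)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index_label="gene", float_format="%.10g")
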