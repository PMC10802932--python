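"""Ligand-receptor interaction scoring between cluster pairs.

For every LR pair and every ordered (sender, receiver) cluster pair the raw
interaction score is the product of the sender's mean ligand expression and
the receiver's mean receptor expression (CP10K cluster means):

    S(l, r, s -> t) = mean_expr[l, s] * mean_expr[r, t]

Each LR pair's scores are then normalized by their sum over all ordered
cluster pairs (self-pairs included, so autocrine signaling is representable):

    N = S / sum over ordered cluster pairs of S

so N sums to 1 per LR pair whenever any score is positive. Ranking incoming
ligands to a receiver and counting interactions for chord-style summaries
operate on this table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .database import PathwayDatabase
from .datasets import ClusterProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["ligand", "receptor", "pathway", "sender", "receiver", "raw_score", "norm_score"]


def interaction_scores(
    profile: ClusterProfile,
    db: PathwayDatabase,
    senders: list[str] | None = None,
) -> pd.DataFrame:
    """Score every LR pair over every ordered (sender, receiver) cluster pair.

    ``senders`` optionally whitelists sender clusters; receivers always range
    over all clusters. Database genes absent from the dataset score zero and
    are reported once via logging; if no database gene is present at all a
    ValidationError lists the missing genes.
    """
    clusters = list(profile.clusters)
    if not clusters:
        raise ValidationError("profile has no clusters")
    send_clusters = clusters if senders is None else sorted(senders)
    unknown = set(send_clusters) - set(clusters)
    if unknown:
        raise ValidationError(f"sender clusters not in profile: {sorted(unknown)}")

    pairs = db.lr_pairs[["ligand", "receptor", "pathway"]].drop_duplicates()
    db_genes = set(pairs["ligand"]) | set(pairs["receptor"])
    present = db_genes & set(profile.mean_expr.index)
    if not present:
        raise ValidationError(
            f"no database ligand/receptor present in dataset; missing: {sorted(db_genes)[:20]}"
        )
    missing = sorted(db_genes - present)
    if missing:
        logger.warning("%d database genes absent from dataset: %s", len(missing), missing[:20])

    def mean_of(genes: pd.Series, cols: list[str]) -> np.ndarray:
        out = np.zeros((len(genes), len(cols)))
        idx = [g in profile.mean_expr.index for g in genes]
        if any(idx):
            found = genes[idx]
            out[np.asarray(idx)] = profile.mean_expr.loc[found, cols].to_numpy()
        return out

    lig_means = mean_of(pairs["ligand"], send_clusters)      # L x S
    rec_means = mean_of(pairs["receptor"], clusters)         # L x R
    raw = np.einsum("ls,lr->lsr", lig_means, rec_means)      # L x S x R

    n_pairs, n_s, n_r = raw.shape
    table = pd.DataFrame(
        {
            "ligand": np.repeat(pairs["ligand"].to_numpy(), n_s * n_r),
            "receptor": np.repeat(pairs["receptor"].to_numpy(), n_s * n_r),
            "pathway": np.repeat(pairs["pathway"].to_numpy(), n_s * n_r),
            "sender": np.tile(np.repeat(send_clusters, n_r), n_pairs),
            "receiver": np.tile(clusters, n_pairs * n_s),
            "raw_score": raw.ravel(),
        }
    )
    pair_sums = raw.reshape(n_pairs, -1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = raw / pair_sums[:, None, None]
    norm[~np.isfinite(norm)] = 0.0
    table["norm_score"] = norm.ravel()
    return table


def rank_incoming_ligands(
    table: pd.DataFrame,
    receiver_cluster: str,
    pathway_filter: set[str] | None = None,
) -> pd.DataFrame:
    """Rows targeting ``receiver_cluster`` ranked by normalized score.

    Ties are broken by (pathway, ligand, receptor, sender) ascending; the
    rank column is 1-based.
    """
    receivers = set(table["receiver"])
    if receiver_cluster not in receivers:
        raise ValidationError(
            f"unknown receiver {receiver_cluster!r}; valid clusters: {sorted(receivers)}"
        )
    rows = table[table["receiver"] == receiver_cluster]
    if pathway_filter is not None:
        rows = rows[rows["pathway"].isin(pathway_filter)]
    rows = rows.sort_values(
        ["norm_score", "pathway", "ligand", "receptor", "sender"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    rows["rank"] = np.arange(1, len(rows) + 1)
    return rows


def count_interactions(
    table: pd.DataFrame,
    receiver_cluster: str | None = None,
    min_norm: float = 0.0,
) -> pd.DataFrame:
    """Count LR pairs with norm_score >= min_norm per (sender, receiver).

    Only interactions with positive raw score are counted (min_norm=0 counts
    all supported interactions). Restricting to a receiver gives the incoming
    edge weights of a chord diagram; without one, all cluster pairs are
    tallied.
    """
    if min_norm < 0:
        raise ValidationError(f"min_norm must be >= 0, got {min_norm}")
    rows = table[(table["raw_score"] > 0) & (table["norm_score"] >= min_norm)]
    if receiver_cluster is not None:
        if receiver_cluster not in set(table["receiver"]):
            raise ValidationError(f"unknown receiver {receiver_cluster!r}")
        rows = rows[rows["receiver"] == receiver_cluster]
    counts = (
        rows.groupby(["sender", "receiver"], sort=True)
        .size()
        .rename("n_interactions")
        .reset_index()
    )
    return counts


def write_scores_tsv(table: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Export with columns ligand, receptor, pathway, sender, receiver, scores, rank."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
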