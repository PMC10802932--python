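"""Multilayer ligand -> receptor -> TF -> target network and pathway ranking.

For one differentiation transition (progenitor receiver plus neighboring
sender clusters) a four-layer directed network is assembled from the pathway
database, gated on expression:

* a ligand enters if expressed (expr_frac >= min_expr_frac) in at least one
  sender cluster;
* a receptor or TF enters if expressed in the receiver;
* a target enters if it passed the DEG filter for the transition and is wired
  to a retained TF.

Nodes without a complete ligand -> target path are pruned iteratively to a
fixed point. Connectivity is then scored bottom-up with normalization at each
layer (each non-empty layer sums to one):

    w(target)   = |log2FC| / sum |log2FC|                 target weights
    u(TF)       ~ mean of w over the TF's targets         (normalized)
    v(receptor) ~ sum of u over the receptor's TFs        (normalized)
    z(ligand)   ~ sum of v over the ligand's receptors    (normalized)
    P(pathway)  ~ sum of z over LR edges annotated to it  (normalized)

A ligand contributes once per annotated LR edge, so promiscuous ligands feed
every pathway they are annotated to. Pathways sorted by P descending give the
activity ranking; the per-layer sum-to-1 normalization makes activities
comparable across runs (e.g. incisor vs molar subsets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import PathwayDatabase
from .datasets import ClusterProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MultilayerNetwork:
    """Pruned four-layer network for one transition.

    lr_edges are (ligand, receptor, pathway) triples; rtf_edges and tft_edges
    are (receptor, tf) and (tf, target) pairs. Node lists are sorted.
    """

    receiver: str
    senders: list[str]
    ligand_nodes: list[str]
    receptor_nodes: list[str]
    tf_nodes: list[str]
    target_nodes: list[str]
    lr_edges: list[tuple[str, str, str]]
    rtf_edges: list[tuple[str, str]]
    tft_edges: list[tuple[str, str]]


@dataclass
class LayerScores:
    """Normalized per-layer connectivity scores (each mapping sums to 1)."""

    target_w: dict[str, float]
    tf_u: dict[str, float]
    receptor_v: dict[str, float]
    ligand_z: dict[str, float]
    pathway_score: dict[str, float]


@dataclass
class PathwayActivity:
    """Ranked pathway activities with provenance.

    table has columns (pathway, activity, rank); activities sum to 1, rank 1
    is the largest activity, ties broken lexicographically.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    details: object = None  # optional PipelineDetails attached by run_toppathways

    @property
    def top_pathway(self) -> str:
        return str(self.table.iloc[0]["pathway"])

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def build_multilayer_network(
    profile: ClusterProfile,
    db: PathwayDatabase,
    deg: pd.DataFrame,
    receiver: str,
    senders: list[str],
    min_expr_frac: float = 0.1,
    allowed_ligands: set[str] | None = None,
) -> MultilayerNetwork:
    """Assemble and prune the network for one transition.

    ``deg`` is the filtered differential result (index = DEG genes, must carry
    log2_fc). ``allowed_ligands`` optionally restricts admission further, e.g.
    to ligands passing an interaction-score gate. Raises ValidationError with
    a layer diagnostic when no complete ligand -> target path exists.
    """
    missing = set(senders + [receiver]) - set(profile.clusters)
    if missing:
        raise ValidationError(f"clusters not in profile: {sorted(missing)}")
    if not senders:
        raise ValidationError("at least one sender cluster is required")
    frac = profile.expr_frac

    def expressed(genes: set[str], cols: list[str]) -> set[str]:
        genes = genes & set(frac.index)
        if not genes:
            return set()
        sub = frac.loc[sorted(genes), cols]
        return set(sub.index[(sub >= min_expr_frac).any(axis=1)])

    ligands = expressed(set(db.lr_pairs["ligand"]), senders)
    if allowed_ligands is not None:
        ligands &= allowed_ligands
    receptors = expressed(set(db.lr_pairs["receptor"]), [receiver])
    tfs = expressed(set(db.receptor_tf["tf"]), [receiver])
    targets = set(deg.index)

    lr = [
        (l, r, p)
        for l, r, p in db.lr_pairs[["ligand", "receptor", "pathway"]].itertuples(index=False)
        if l in ligands and r in receptors
    ]
    rtf = [
        (r, t)
        for r, t in db.receptor_tf[["receptor", "tf"]].drop_duplicates().itertuples(index=False)
        if r in receptors and t in tfs
    ]
    tft = [
        (t, g)
        for t, g in db.tf_target[["tf", "target"]].drop_duplicates().itertuples(index=False)
        if t in tfs and g in targets
    ]

    initial_empty = [
        name
        for name, nodes in (
            ("ligand", ligands), ("receptor", receptors), ("tf", tfs), ("target", targets),
        )
        if not nodes
    ]

    # prune to the fixed point where every node lies on a complete L->R->TF->G path
    while True:
        tf_ok = {t for _, t in rtf} & {t for t, _ in tft}
        rec_ok = {r for _, r, _ in lr} & {r for r, t in rtf if t in tf_ok}
        lig_ok = {l for l, r, _ in lr if r in rec_ok}
        new_lr = [(l, r, p) for l, r, p in lr if l in lig_ok and r in rec_ok]
        new_rtf = [(r, t) for r, t in rtf if r in rec_ok and t in tf_ok]
        new_tft = [(t, g) for t, g in tft if t in tf_ok]
        if (len(new_lr), len(new_rtf), len(new_tft)) == (len(lr), len(rtf), len(tft)):
            lr, rtf, tft = new_lr, new_rtf, new_tft
            break
        lr, rtf, tft = new_lr, new_rtf, new_tft

    if not lr or not tft:
        layer = initial_empty[0] if initial_empty else (
            "target" if not tft else "tf" if not rtf else "ligand/receptor"
        )
        raise ValidationError(
            f"no complete ligand->target path for receiver {receiver!r}: "
            f"the {layer} layer emptied first"
        )

    return MultilayerNetwork(
        receiver=receiver,
        senders=sorted(senders),
        ligand_nodes=sorted({l for l, _, _ in lr}),
        receptor_nodes=sorted({r for _, r, _ in lr}),
        tf_nodes=sorted({t for t, _ in tft}),
        target_nodes=sorted({g for _, g in tft}),
        lr_edges=sorted(lr),
        rtf_edges=sorted(rtf),
        tft_edges=sorted(tft),
    )


def _normalize(raw: dict[str, float], layer: str) -> dict[str, float]:
    total = sum(raw.values())
    if not raw:
        return {}
    if total <= 0:
        # degenerate: all raw scores zero (e.g. every DEG with log2FC == 0)
        logger.warning("layer %s has zero total raw score; using uniform weights", layer)
        return {k: 1.0 / len(raw) for k in raw}
    return {k: v / total for k, v in raw.items()}


def score_layers(
    network: MultilayerNetwork, deg: pd.DataFrame, tf_mode: str = "mean"
) -> LayerScores:
    """Bottom-up connectivity scores with per-layer sum-to-1 normalization.

    ``tf_mode`` selects the TF raw score: 'mean' (default) averages the
    normalized target weights over the TF's targets; 'count' uses the number
    of targets instead.
    """
    if tf_mode not in ("mean", "count"):
        raise ValidationError(f"tf_mode must be 'mean' or 'count', got {tf_mode!r}")
    missing = set(network.target_nodes) - set(deg.index)
    if missing:
        raise ValidationError(
            f"network targets missing from differential result: {sorted(missing)[:10]}"
        )
    w_raw = {g: abs(float(deg.loc[g, "log2_fc"])) for g in network.target_nodes}
    w = _normalize(w_raw, "target")

    tf_targets: dict[str, list[str]] = {}
    for t, g in network.tft_edges:
        tf_targets.setdefault(t, []).append(g)
    if tf_mode == "mean":
        u_raw = {t: float(np.mean([w[g] for g in gs])) for t, gs in tf_targets.items()}
    else:
        u_raw = {t: float(len(gs)) for t, gs in tf_targets.items()}
    u = _normalize(u_raw, "tf")

    rec_tfs: dict[str, list[str]] = {}
    for r, t in network.rtf_edges:
        rec_tfs.setdefault(r, []).append(t)
    v_raw = {r: sum(u[t] for t in ts) for r, ts in rec_tfs.items()}
    v = _normalize(v_raw, "receptor")

    lig_recs: dict[str, set[str]] = {}
    for l, r, _ in network.lr_edges:
        lig_recs.setdefault(l, set()).add(r)
    z_raw = {l: sum(v[r] for r in rs) for l, rs in lig_recs.items()}
    z = _normalize(z_raw, "ligand")

    p_raw: dict[str, float] = {}
    for l, _, pw in network.lr_edges:
        p_raw[pw] = p_raw.get(pw, 0.0) + z[l]
    pathway_score = _normalize(p_raw, "pathway")

    return LayerScores(
        target_w=w, tf_u=u, receptor_v=v, ligand_z=z, pathway_score=pathway_score
    )


def rank_pathways(layers: LayerScores, provenance: dict | None = None) -> PathwayActivity:
    """Sort pathways by activity descending; 1-based ranks, lexicographic ties."""
    items = sorted(layers.pathway_score.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(
        {
            "pathway": [k for k, _ in items],
            "activity": [v for _, v in items],
            "rank": np.arange(1, len(items) + 1),
        }
    )
    return PathwayActivity(table=table, provenance=dict(provenance or {}))
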