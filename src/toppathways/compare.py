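"""The end-to-end pipeline for one transition, and subset-vs-subset comparison.

``run_toppathways`` composes the full analysis for a differentiation
transition (progenitor, mature target, neighboring senders): optional subset
restriction -> QC -> CP10K normalization -> cluster profile -> interaction
scores -> progenitor-vs-mature DE -> DEG filter -> multilayer network ->
layer scoring -> pathway ranking. Each stage failure is re-raised labeled
with its stage name. Runs are deterministic given (dataset, database,
transition, params).

Comparative analysis runs the same transition per metadata subset (e.g.
incisor vs molar) against one shared database and parameter set (enforced by
checksum) and reports per-pathway activity ratios with a small smoothing
constant so pathways absent from one run stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .database import PathwayDatabase
from .datasets import ExpressionDataset, QCParams, cluster_profile, normalize_cp10k, qc_filter
from .de import differential_expression, filter_deg
from .errors import StageError, ValidationError
from .interactions import interaction_scores
from .network import (
    MultilayerNetwork,
    PathwayActivity,
    build_multilayer_network,
    rank_pathways,
    score_layers,
)

logger = logging.getLogger(__name__)


@dataclass
class TransitionSpec:
    """A differentiation transition: progenitor, mature target and senders."""

    name: str
    progenitor_cluster: str
    mature_cluster: str
    sender_clusters: list[str]
    subset: str | None = None

    def __post_init__(self) -> None:
        if self.progenitor_cluster == self.mature_cluster:
            raise ValidationError(
                f"transition {self.name!r}: progenitor and mature cluster are both "
                f"{self.progenitor_cluster!r}"
            )
        if not self.sender_clusters:
            raise ValidationError(f"transition {self.name!r}: no sender clusters")


@dataclass
class PipelineParams:
    """Tunable thresholds for one pipeline run.

    qc              UMI band and mitochondrial prefix
    max_fdr/min_fc  the DEG filter (defaults FDR < 0.1, FC > 2)
    epsilon         fold-change pseudocount in CP10K units
    min_expr_frac   expression-fraction gate for network admission
    min_norm_score  optional gate: ligands need an interaction of at least
                    this normalized score into the receiver to enter the
                    network (None decouples the two stages)
    """

    qc: QCParams = field(default_factory=QCParams)
    max_fdr: float = 0.1
    min_fc: float = 2.0
    two_sided_fc: bool = True
    epsilon: float = 0.01
    min_expr_frac: float = 0.1
    min_norm_score: float | None = None
    tf_mode: str = "mean"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineDetails:
    """Intermediate products of a run, for exports and inspection."""

    dataset: ExpressionDataset
    profile: object
    interactions: pd.DataFrame
    deg_full: pd.DataFrame
    deg: pd.DataFrame
    network: MultilayerNetwork
    layers: object


def subset_dataset(ds: ExpressionDataset, field_name: str, value: str) -> ExpressionDataset:
    """Restrict to cells whose ``field_name`` (cluster/stage/subset) equals ``value``.

    Genes are unchanged; per-cell CP10K normalization is subset-invariant so
    an existing normalized layer is carried over.
    """
    if field_name not in ("cluster", "stage", "subset"):
        raise ValidationError(
            f"field must be one of cluster, stage, subset; got {field_name!r}"
        )
    values = set(ds.cells[field_name])
    if value not in values:
        raise ValidationError(
            f"{field_name} value {value!r} not present; available: {sorted(values)}"
        )
    keep = (ds.cells[field_name] == value).to_numpy()
    out = ExpressionDataset(
        counts=ds.counts[:, keep].tocsr(),
        gene_ids=ds.gene_ids,
        cells=ds.cells.loc[keep].reset_index(drop=True).copy(),
        stage_order=list(ds.stage_order),
        normalized=None if ds.normalized is None else ds.normalized[:, keep].tocsr(),
    )
    return out


def run_toppathways(
    ds: ExpressionDataset,
    db: PathwayDatabase,
    spec: TransitionSpec,
    params: PipelineParams | None = None,
    seed: int | None = None,
) -> PathwayActivity:
    """Full pipeline for one transition; returns ranked pathway activities.

    The result carries provenance (transition, parameters, database checksum,
    seed, package version) and a ``details`` attribute with all intermediate
    tables. Stage failures raise StageError naming the failing stage.
    """
    params = params or PipelineParams()
    stage = "setup"
    try:
        if spec.subset is not None:
            stage = "subset"
            ds = subset_dataset(ds, "subset", spec.subset)
        stage = "qc"
        ds = qc_filter(ds, params.qc)
        stage = "normalize"
        ds = normalize_cp10k(ds)
        stage = "profile"
        profile = cluster_profile(ds)
        missing = {
            spec.progenitor_cluster,
            spec.mature_cluster,
            *spec.sender_clusters,
        } - set(profile.clusters)
        if missing:
            raise ValidationError(f"clusters named by the transition are absent: {sorted(missing)}")
        stage = "interaction_scores"
        scores = interaction_scores(profile, db)
        allowed = None
        if params.min_norm_score is not None:
            gate = scores[
                (scores["receiver"] == spec.progenitor_cluster)
                & (scores["norm_score"] >= params.min_norm_score)
            ]
            allowed = set(gate["ligand"])
        stage = "differential_expression"
        deg_full = differential_expression(
            ds, spec.progenitor_cluster, spec.mature_cluster, epsilon=params.epsilon
        )
        stage = "filter_deg"
        deg = filter_deg(deg_full, params.max_fdr, params.min_fc, params.two_sided_fc)
        stage = "build_network"
        network = build_multilayer_network(
            profile,
            db,
            deg,
            receiver=spec.progenitor_cluster,
            senders=spec.sender_clusters,
            min_expr_frac=params.min_expr_frac,
            allowed_ligands=allowed,
        )
        stage = "score_layers"
        layers = score_layers(network, deg, tf_mode=params.tf_mode)
        stage = "rank_pathways"
        activity = rank_pathways(
            layers,
            provenance={
                "transition": spec.name,
                "subset": spec.subset,
                "progenitor": spec.progenitor_cluster,
                "mature": spec.mature_cluster,
                "senders": sorted(spec.sender_clusters),
                "params": params.to_dict(),
                "db_checksum": db.checksum(),
                "seed": seed,
                "version": __version__,
            },
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, spec.name, exc) from exc
    activity.details = PipelineDetails(
        dataset=ds,
        profile=profile,
        interactions=scores,
        deg_full=deg_full,
        deg=deg,
        network=network,
        layers=layers,
    )
    return activity


@dataclass
class ActivityComparison:
    """Per-pathway activity ratio between two runs (subsets a and b)."""

    table: pd.DataFrame
    label_a: str
    label_b: str
    delta: float


def pathway_activity_ratio(
    act_a: PathwayActivity,
    act_b: PathwayActivity,
    delta: float = 1e-6,
    labels: tuple[str, str] = ("a", "b"),
) -> ActivityComparison:
    """ratio = (activity_a + delta) / (activity_b + delta) per pathway.

    Both runs must come from the same database (checksum enforced); pathways
    absent from one run get activity 0 there and are flagged.
    """
    ck_a = act_a.provenance.get("db_checksum")
    ck_b = act_b.provenance.get("db_checksum")
    if ck_a != ck_b:
        raise ValidationError(
            "activity tables come from different pathway databases "
            f"({ck_a!r} vs {ck_b!r}); ratios would be meaningless"
        )
    a = act_a.table.set_index("pathway")["activity"]
    b = act_b.table.set_index("pathway")["activity"]
    pathways = sorted(set(a.index) | set(b.index))
    a = a.reindex(pathways, fill_value=0.0)
    b = b.reindex(pathways, fill_value=0.0)
    table = pd.DataFrame(
        {
            "pathway": pathways,
            "activity_a": a.to_numpy(),
            "activity_b": b.to_numpy(),
            "ratio_a_over_b": (a.to_numpy() + delta) / (b.to_numpy() + delta),
            "present_a": a.to_numpy() > 0,
            "present_b": b.to_numpy() > 0,
        }
    )
    return ActivityComparison(table=table, label_a=labels[0], label_b=labels[1], delta=delta)
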