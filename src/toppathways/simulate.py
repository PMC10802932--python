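"""Synthetic sci-RNA-seq-like datasets with planted signaling ground truth.

Counts are negative binomial: gene g in cell c is drawn NB with mean
mu[g, c] and dispersion phi (variance mu + mu^2/phi). Low baseline means give
the sparsity typical of combinatorial-indexing data without an explicit
dropout layer. Cluster structure, planted signaling and library size enter
through the mean:

* every gene starts at a baseline mean mu0 in every (subset, cluster) group;
* a planted signal multiplies its pathway's ligand genes by alpha >= 1 in the
  sender cluster and its receptor genes by beta >= 1 in the receiver
  (progenitor) cluster, and shifts its responsive target genes by f in log2
  (mean x 2^f) in the mature cluster — the differential expression the
  downstream network scoring must recover;
* maturation/progenitor marker genes follow configurable per-cluster means,
  planting a maturation gradient;
* each cell's means are rescaled so its expected UMI total is drawn uniformly
  from ``umi_target``, emulating library-size variation.

Decoy pathways are wired into the database exactly like planted ones but
receive no boosts, so under the null all pathways are exchangeable and the
top-1 ranking is uniform — which is what makes the null-calibration check
meaningful. Stage and subset labels follow a per-stratum proportion schedule
with deterministic largest-remainder allocation, so the planted
first-appearance stage of each cell type is exact, not sampled.

One global seed feeds a single generator stream consumed in fixed order
(per-cell scale factors first, then the count matrix, genes outer / cells
inner), so identical (config, seed) reproduce byte-identical output on any
platform with IEEE doubles.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .compare import PipelineParams, TransitionSpec, run_toppathways
from .database import PathwayDatabase, write_pathway_database
from .datasets import ExpressionDataset, write_expression
from .errors import ValidationError

STAGES = ["9-11gw", "12-13gw", "14-16gw", "17-19gw", "20-22gw"]
CLUSTERS = ["DEM", "DP", "EK", "IEE", "OB", "POB"]
PATHWAY_NAMES = ["FGF", "BMP", "WNT", "HH", "NOTCH", "EGF", "ROBO", "TGFB"]


@dataclass
class PathwaySpec:
    """Gene-set sizes and wiring for one pathway in the synthetic database.

    ``tf_wiring`` is 'full' (every TF regulates every target) or 'one_to_one'
    (TF j regulates target j only; requires n_tfs == n_targets). One-to-one
    wiring makes the number of responsive targets visible to the connectivity
    scoring: a TF whose sole target is not differentially expressed prunes
    away, so target multiplicity reaches the receptor-layer sum instead of
    being averaged out at the TF layer.
    """

    name: str
    n_ligands: int = 2
    n_receptors: int = 2
    n_tfs: int = 2
    n_targets: int = 6
    tf_wiring: str = "full"


@dataclass
class PlantedSignal:
    """One planted sender -> receiver signal with downstream target response.

    ``subset`` restricts the effect to one metadata subset (None = all);
    ``n_affected_targets`` limits the target response to the first k target
    genes of the pathway (None = all), which lets comparative harnesses scale
    the total planted effect between subsets.
    """

    pathway: str
    sender_cluster: str
    receiver_cluster: str
    ligand_boost: float = 1.0
    receptor_boost: float = 1.0
    target_log2fc: float = 0.0
    subset: str | None = None
    n_affected_targets: int | None = None


@dataclass
class Stratum:
    """Cell allocation for one (subset, stage): total cells and type fractions."""

    subset: str
    stage: str
    n_cells: int
    fractions: dict[str, float]


@dataclass
class SimulationConfig:
    clusters: list[str] = field(default_factory=lambda: list(CLUSTERS))
    stage_order: list[str] = field(default_factory=lambda: list(STAGES))
    strata: list[Stratum] = field(default_factory=list)
    pathways: list[PathwaySpec] = field(default_factory=list)
    planted: list[PlantedSignal] = field(default_factory=list)
    progenitor_cluster: str = "DP"
    mature_cluster: str = "POB"
    sender_clusters: list[str] = field(default_factory=lambda: list(CLUSTERS))
    n_background_genes: int = 300
    baseline_mean: float = 0.5
    target_baseline_mean: float = 0.5
    dispersion: float = 2.0
    n_maturation_markers: int = 5
    n_progenitor_markers: int = 5
    maturation_marker_means: dict[str, float] = field(default_factory=dict)
    progenitor_marker_means: dict[str, float] = field(default_factory=dict)
    umi_target: tuple[float, float] = (200.0, 1000.0)
    presence_threshold: float = 0.01
    expected_top_pathway: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_mean <= 0 or self.target_baseline_mean <= 0:
            raise ValidationError("baseline means must be positive")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not self.strata:
            raise ValidationError("at least one stratum is required")
        if self.umi_target[0] <= 0 or self.umi_target[0] > self.umi_target[1]:
            raise ValidationError(f"invalid umi_target range {self.umi_target}")
        names = {p.name for p in self.pathways}
        if len(names) != len(self.pathways):
            raise ValidationError("duplicate pathway names")
        for pw in self.pathways:
            if pw.tf_wiring not in ("full", "one_to_one"):
                raise ValidationError(f"pathway {pw.name}: unknown tf_wiring {pw.tf_wiring!r}")
            if pw.tf_wiring == "one_to_one" and pw.n_tfs != pw.n_targets:
                raise ValidationError(
                    f"pathway {pw.name}: one_to_one wiring needs n_tfs == n_targets"
                )
        for st in self.strata:
            total = sum(st.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"stratum ({st.subset}, {st.stage}): fractions sum to {total!r}, not 1"
                )
            unknown = set(st.fractions) - set(self.clusters)
            if unknown:
                raise ValidationError(
                    f"stratum ({st.subset}, {st.stage}) names unknown clusters {sorted(unknown)}"
                )
            if st.stage not in self.stage_order:
                raise ValidationError(f"stage {st.stage!r} absent from stage_order")
        for ps in self.planted:
            if ps.pathway not in names:
                raise ValidationError(f"planted pathway {ps.pathway!r} not configured")
            if ps.ligand_boost < 1 or ps.receptor_boost < 1:
                raise ValidationError("planted boosts must be >= 1")
            for cl in (ps.sender_cluster, ps.receiver_cluster):
                if cl not in self.clusters:
                    raise ValidationError(f"planted cluster {cl!r} not configured")
        if self.progenitor_cluster == self.mature_cluster:
            raise ValidationError("progenitor and mature cluster must differ")

    def default_transition(self, subset: str | None = None) -> TransitionSpec:
        return TransitionSpec(
            name=f"{self.progenitor_cluster}_to_{self.mature_cluster}",
            progenitor_cluster=self.progenitor_cluster,
            mature_cluster=self.mature_cluster,
            sender_clusters=list(self.sender_clusters),
            subset=subset,
        )


@dataclass
class SyntheticTruth:
    """Planted parameters and derived expectations for recovery tests."""

    config: SimulationConfig
    seed: int
    gene_roles: pd.DataFrame          # gene, role, pathway
    true_de: pd.DataFrame             # gene, subset, log2fc (planted responses)
    first_appearance: dict            # subset -> cell_type -> stage or "absent"
    expected_top_pathway: str | None
    cell_scale: np.ndarray            # per-cell library scale factors s_c
    base_mean: pd.DataFrame           # gene x (subset, cluster) unscaled NB means

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "expected_top_pathway": self.expected_top_pathway,
            "first_appearance": self.first_appearance,
            "gene_roles": self.gene_roles.to_dict(orient="records"),
            "true_de": self.true_de.to_dict(orient="records"),
            "config": _config_to_dict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["umi_target"] = list(config.umi_target)
    return d


def _allocate(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder integer allocation; deterministic (ties by name)."""
    items = sorted(fractions.items())
    base = {c: math.floor(f * n) for c, f in items}
    remainders = sorted(items, key=lambda cf: (-(cf[1] * n - base[cf[0]]), cf[0]))
    short = n - sum(base.values())
    for c, _ in remainders[:short]:
        base[c] += 1
    return base


def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    rows: list[tuple[str, str, str]] = []
    for i in range(config.n_background_genes):
        rows.append((f"BG{i:04d}", "background", ""))
    for pw in config.pathways:
        for j in range(pw.n_ligands):
            rows.append((f"{pw.name}_L{j + 1}", "ligand", pw.name))
        for j in range(pw.n_receptors):
            rows.append((f"{pw.name}_R{j + 1}", "receptor", pw.name))
        for j in range(pw.n_tfs):
            rows.append((f"{pw.name}_TF{j + 1}", "tf", pw.name))
        for j in range(pw.n_targets):
            rows.append((f"{pw.name}_T{j + 1:02d}", "target", pw.name))
    for j in range(config.n_maturation_markers):
        rows.append((f"MATM{j + 1}", "marker_maturation", ""))
    for j in range(config.n_progenitor_markers):
        rows.append((f"PROGM{j + 1}", "marker_progenitor", ""))
    return pd.DataFrame(rows, columns=["gene", "role", "pathway"])


def _build_database(config: SimulationConfig) -> PathwayDatabase:
    lr, rtf, tft = [], [], []
    for pw in config.pathways:
        ligs = [f"{pw.name}_L{j + 1}" for j in range(pw.n_ligands)]
        recs = [f"{pw.name}_R{j + 1}" for j in range(pw.n_receptors)]
        tfs = [f"{pw.name}_TF{j + 1}" for j in range(pw.n_tfs)]
        tgts = [f"{pw.name}_T{j + 1:02d}" for j in range(pw.n_targets)]
        lr += [(l, r, pw.name) for l in ligs for r in recs]
        rtf += [(r, t) for r in recs for t in tfs]
        if pw.tf_wiring == "one_to_one":
            tft += list(zip(tfs, tgts))
        else:
            tft += [(t, g) for t in tfs for g in tgts]
    db = PathwayDatabase(
        lr_pairs=pd.DataFrame(lr, columns=["ligand", "receptor", "pathway"]),
        receptor_tf=pd.DataFrame(rtf, columns=["receptor", "tf"]),
        tf_target=pd.DataFrame(tft, columns=["tf", "target"]),
    )
    db.validate()
    return db


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionDataset, PathwayDatabase, SyntheticTruth]:
    """Draw one dataset plus its database and ground truth from the config."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    genes = _gene_table(config)
    gene_ids = pd.Index(genes["gene"], name="gene_id")
    G = len(gene_ids)

    # --- cells: deterministic allocation per stratum -------------------------
    cell_rows = []
    for st in config.strata:
        alloc = _allocate(st.fractions, st.n_cells)
        for cluster in sorted(alloc):
            for _ in range(alloc[cluster]):
                cell_rows.append((cluster, st.stage, st.subset))
    cells = pd.DataFrame(cell_rows, columns=["cluster", "stage", "subset"])
    cells.insert(0, "cell_id", [f"cell{i:06d}" for i in range(len(cells))])
    C = len(cells)

    # --- unscaled NB means per (subset, cluster) group ----------------------
    subsets = sorted({st.subset for st in config.strata})
    groups = [(sub, cl) for sub in subsets for cl in config.clusters]
    group_index = {g: i for i, g in enumerate(groups)}
    base = np.full((G, len(groups)), config.baseline_mean)
    role = genes["role"].to_numpy()
    base[role == "target"] = config.target_baseline_mean
    for j, (sub, cl) in enumerate(groups):
        mat_mean = config.maturation_marker_means.get(cl)
        if mat_mean is not None:
            base[role == "marker_maturation", j] = mat_mean
        prog_mean = config.progenitor_marker_means.get(cl)
        if prog_mean is not None:
            base[role == "marker_progenitor", j] = prog_mean

    true_de_rows = []
    for ps in config.planted:
        subs = subsets if ps.subset is None else [ps.subset]
        lig_rows = ((genes["role"] == "ligand") & (genes["pathway"] == ps.pathway)).to_numpy()
        rec_rows = ((genes["role"] == "receptor") & (genes["pathway"] == ps.pathway)).to_numpy()
        tgt_names = genes.loc[
            (genes["role"] == "target") & (genes["pathway"] == ps.pathway), "gene"
        ].tolist()
        affected = tgt_names if ps.n_affected_targets is None else tgt_names[: ps.n_affected_targets]
        tgt_rows = genes["gene"].isin(affected).to_numpy()
        for sub in subs:
            base[lig_rows, group_index[(sub, ps.sender_cluster)]] *= ps.ligand_boost
            base[rec_rows, group_index[(sub, ps.receiver_cluster)]] *= ps.receptor_boost
            if ps.target_log2fc != 0.0:
                base[tgt_rows, group_index[(sub, config.mature_cluster)]] *= 2.0 ** ps.target_log2fc
                for g in affected:
                    true_de_rows.append((g, sub, ps.target_log2fc))

    # --- sample counts: one stream, scales first, then genes x cells --------
    cell_groups = np.array(
        [group_index[(sub, cl)] for sub, cl in zip(cells["subset"], cells["cluster"])]
    )
    group_sums = base.sum(axis=0)
    u = rng.uniform(config.umi_target[0], config.umi_target[1], size=C)
    scale = u / group_sums[cell_groups]
    mu = base[:, cell_groups] * scale[None, :]
    phi = config.dispersion
    counts_dense = rng.negative_binomial(phi, phi / (phi + mu), size=(G, C))
    counts = sp.csr_matrix(counts_dense.astype(np.int64))
    cells["umi"] = np.asarray(counts.sum(axis=0)).ravel().astype(np.int64)

    ds = ExpressionDataset(
        counts=counts,
        gene_ids=gene_ids,
        cells=cells[["cell_id", "cluster", "stage", "subset", "umi"]],
        stage_order=list(config.stage_order),
    )
    ds.validate()

    db = _build_database(config)

    # --- exact first-appearance truth from the integer allocations ----------
    first: dict[str, dict[str, str]] = {}
    for sub in subsets:
        first[sub] = {}
        for cl in config.clusters:
            found = "absent"
            for stage in config.stage_order:
                strata = [s for s in config.strata if s.subset == sub and s.stage == stage]
                n_cl = sum(_allocate(s.fractions, s.n_cells).get(cl, 0) for s in strata)
                n_tot = sum(s.n_cells for s in strata)
                if n_tot and n_cl / n_tot >= config.presence_threshold:
                    found = stage
                    break
            first[sub][cl] = found

    truth = SyntheticTruth(
        config=config,
        seed=seed,
        gene_roles=genes,
        true_de=pd.DataFrame(true_de_rows, columns=["gene", "subset", "log2fc"]),
        first_appearance=first,
        expected_top_pathway=config.expected_top_pathway,
        cell_scale=scale,
        base_mean=pd.DataFrame(
            base, index=gene_ids, columns=pd.MultiIndex.from_tuples(groups)
        ),
    )
    return ds, db, truth


def write_simulation(
    ds: ExpressionDataset, db: PathwayDatabase, truth: SyntheticTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write the dataset (mtx + TSVs), database CSVs and truth JSON."""
    outdir = Path(outdir)
    paths = write_expression(ds, outdir)
    paths |= write_pathway_database(db, outdir)
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths


def planted_recovery_rate(
    config: SimulationConfig,
    n_seeds: int,
    transition: TransitionSpec | None = None,
    params: PipelineParams | None = None,
    base_seed: int = 0,
) -> float:
    """Fraction of seeds where the planted pathway ranks first.

    Runs the full pipeline on datasets simulated with seeds base_seed ..
    base_seed + n_seeds - 1. Requires the config to designate exactly one
    expected top pathway.
    """
    if config.expected_top_pathway is None:
        raise ValidationError("config designates no expected top pathway")
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    spec = transition or config.default_transition()
    hits = 0
    for i in range(n_seeds):
        ds, db, _ = simulate_dataset(config, seed=base_seed + i)
        activity = run_toppathways(ds, db, spec, params=params)
        hits += int(activity.top_pathway == config.expected_top_pathway)
    return hits / n_seeds


# ---------------------------------------------------------------------------
# Study configurations
# ---------------------------------------------------------------------------

def default_config(cells_per_cluster: int = 333, seed: int = 0) -> SimulationConfig:
    """Six clusters, ~2,000 cells, 8 pathways, one planted FGF signal.

    The planted signal sends FGF ligands from the enamel knot (EK) into the
    dental papilla (DP) progenitor (ligand boost 8, receptor boost 4) with a
    3 log2-fold target response in the maturing preodontoblast (POB); the
    other 7 pathways are decoys at baseline.
    """
    n = cells_per_cluster * len(CLUSTERS)
    return SimulationConfig(
        strata=[
            Stratum("incisor", "12-13gw", n, {c: 1.0 / len(CLUSTERS) for c in CLUSTERS})
        ],
        pathways=[PathwaySpec(name) for name in PATHWAY_NAMES],
        planted=[
            PlantedSignal(
                "FGF", "EK", "DP", ligand_boost=8.0, receptor_boost=4.0, target_log2fc=3.0
            )
        ],
        maturation_marker_means={"DP": 0.5, "POB": 1.5, "OB": 4.5},
        progenitor_marker_means={"DP": 4.5, "POB": 1.5, "OB": 0.5},
        expected_top_pathway="FGF",
        seed=seed,
    )


def null_config(cells_per_cluster: int = 333, seed: int = 0) -> SimulationConfig:
    """As default_config but with no effect: all 8 pathways exchangeable.

    The "planted" FGF label is retained (boosts 1, no target response) so the
    top-1 recovery rate of the label estimates the uniform null of 1/8.
    """
    config = default_config(cells_per_cluster, seed)
    config.planted = [
        PlantedSignal("FGF", "EK", "DP", ligand_boost=1.0, receptor_boost=1.0, target_log2fc=0.0)
    ]
    return config


def null_params() -> PipelineParams:
    """Pipeline parameters for null calibration: the DEG filter is disabled.

    Under the null the standard filter (FDR < 0.1, FC > 2) correctly empties
    the target layer; disabling it lets every pathway's targets enter with
    noise-driven weights, so the ranking is exchangeable across pathways.
    """
    return PipelineParams(max_fdr=1.0 + 1e-9, min_fc=1.0)


def ratio_config(rho: int, cells_per_cluster: int = 166, seed: int = 0) -> SimulationConfig:
    """Two subsets with the planted FGF signaling effect scaled rho:1.

    The FGF pathway carries 16 one-to-one TF -> target channels; 2*rho of the
    targets respond (at 2.5 log2-fold) in the incisor vs 2 in the molar, so
    the total planted effect (sum of target |log2FC|) is in ratio rho:1. The
    remaining 7 pathways respond identically in both subsets (all 6 targets
    at 2.5 log2-fold) and serve as the shared reference against which the
    normalized activities of the two runs are compared.
    """
    if not (1 <= rho <= 8):
        raise ValidationError("rho must be in [1, 8] so 2*rho targets fit the pathway")
    n = cells_per_cluster * len(CLUSTERS)
    frac = {c: 1.0 / len(CLUSTERS) for c in CLUSTERS}
    pathways = [
        PathwaySpec(
            name,
            n_tfs=16 if name == "FGF" else 6,
            n_targets=16 if name == "FGF" else 6,
            tf_wiring="one_to_one",
        )
        for name in PATHWAY_NAMES
    ]
    planted = [
        PlantedSignal(
            "FGF", "EK", "DP", 8.0, 4.0, target_log2fc=2.5,
            subset="incisor", n_affected_targets=2 * rho,
        ),
        PlantedSignal(
            "FGF", "EK", "DP", 8.0, 4.0, target_log2fc=2.5,
            subset="molar", n_affected_targets=2,
        ),
    ]
    planted += [
        PlantedSignal(name, "EK", "DP", 1.0, 1.0, target_log2fc=2.5)
        for name in PATHWAY_NAMES
        if name != "FGF"
    ]
    return SimulationConfig(
        strata=[
            Stratum("incisor", "12-13gw", n, frac),
            Stratum("molar", "12-13gw", n, frac),
        ],
        pathways=pathways,
        planted=planted,
        seed=seed,
    )


def kinetics_config(cells_per_stratum: int = 120, seed: int = 0) -> SimulationConfig:
    """Two subsets, five stages, a planted OB appearance delay and marker gradient.

    Mature odontoblasts (OB) first reach the 1% presence threshold at the
    third stage in the incisor but only at the fourth in the molar; marker
    means rise DP -> POB -> OB (and fall for progenitor markers), planting a
    strictly increasing maturation gradient.
    """
    ob_schedule = {
        "incisor": [0.0, 0.0, 0.05, 0.10, 0.15],
        "molar": [0.0, 0.0, 0.0, 0.05, 0.10],
    }
    base_other = {"DEM": 0.20, "DP": 0.25, "POB": 0.20, "EK": 0.20, "IEE": 0.15}
    strata = []
    for subset, schedule in ob_schedule.items():
        for stage, ob_frac in zip(STAGES, schedule):
            fractions = {c: f * (1.0 - ob_frac) for c, f in base_other.items()}
            fractions["OB"] = ob_frac
            strata.append(Stratum(subset, stage, cells_per_stratum, fractions))
    return SimulationConfig(
        strata=strata,
        pathways=[PathwaySpec(name) for name in PATHWAY_NAMES],
        planted=[],
        maturation_marker_means={"DP": 0.5, "POB": 1.5, "OB": 4.5},
        progenitor_marker_means={"DP": 4.5, "POB": 1.5, "OB": 0.5},
        seed=seed,
    )
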