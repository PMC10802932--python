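"""Independent brute-force oracles and random-instance generators.

Everything here is written straight from the scoring definitions with plain
loops, deliberately sharing no code with the package, so it can serve as the
reference the implementation is checked against.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from toppathways.network import MultilayerNetwork


# ---------------------------------------------------------------------------
# interaction scoring: double-loop oracle
# ---------------------------------------------------------------------------

def interaction_scores_oracle(mean_expr: pd.DataFrame, lr_pairs: pd.DataFrame) -> dict:
    """raw and normalized scores keyed by (ligand, receptor, pathway, sender, receiver)."""
    clusters = list(mean_expr.columns)
    raw = {}
    for _, row in lr_pairs.iterrows():
        lig, rec, pw = row["ligand"], row["receptor"], row["pathway"]
        for s in clusters:
            for t in clusters:
                lv = mean_expr.loc[lig, s] if lig in mean_expr.index else 0.0
                rv = mean_expr.loc[rec, t] if rec in mean_expr.index else 0.0
                raw[(lig, rec, pw, s, t)] = lv * rv
    out = {}
    for _, row in lr_pairs.iterrows():
        lig, rec, pw = row["ligand"], row["receptor"], row["pathway"]
        total = sum(raw[(lig, rec, pw, s, t)] for s in clusters for t in clusters)
        for s in clusters:
            for t in clusters:
                r = raw[(lig, rec, pw, s, t)]
                out[(lig, rec, pw, s, t)] = (r, r / total if total > 0 else 0.0)
    return out


# ---------------------------------------------------------------------------
# rank-sum: exact enumeration oracle
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def exact_ranksum_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p over all assignments of len(x) labels."""
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2.0
    observed = abs(ranks[:n1].sum() - mu)
    extreme = sum(
        1
        for idx in combinations(range(n), n1)
        if abs(sum(ranks[i] for i in idx) - mu) >= observed - 1e-9
    )
    return extreme / comb(n, n1)


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """BH step-up from the definition: sort, q_(i) = min over j>=i of p_(j)*m/j."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(1.0, running)
    out = np.empty(m)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# multilayer scoring: brute-force traversal oracle + random networks
# ---------------------------------------------------------------------------

def layer_scores_oracle(network: MultilayerNetwork, deg: pd.DataFrame) -> dict:
    """Scores from the formulas alone: w from |log2FC|, u mean, v/z/P sums."""

    def norm(d):
        total = sum(d.values())
        if not d:
            return {}
        if total <= 0:
            return {k: 1.0 / len(d) for k in d}
        return {k: v / total for k, v in d.items()}

    w = norm({g: abs(deg.loc[g, "log2_fc"]) for g in network.target_nodes})
    u_raw = {}
    for tf in network.tf_nodes:
        targets = [g for t, g in network.tft_edges if t == tf]
        u_raw[tf] = sum(w[g] for g in targets) / len(targets)
    u = norm(u_raw)
    v_raw = {}
    for r in network.receptor_nodes:
        tfs = [t for rr, t in network.rtf_edges if rr == r]
        v_raw[r] = sum(u[t] for t in tfs)
    v = norm(v_raw)
    z_raw = {}
    for l in network.ligand_nodes:
        recs = {r for ll, r, _ in network.lr_edges if ll == l}
        z_raw[l] = sum(v[r] for r in recs)
    z = norm(z_raw)
    p_raw = {}
    for l, _, pw in network.lr_edges:
        p_raw[pw] = p_raw.get(pw, 0.0) + z[l]
    return {"w": w, "u": u, "v": v, "z": z, "P": norm(p_raw)}


def random_network(rng: np.random.Generator, max_per_layer: int = 6):
    """A random pruned-valid multilayer network plus a matching DEG table.

    Every TF gets at least one receptor and one target; every receptor gets a
    ligand and a TF; every target a TF — so the instance is already at the
    pruning fixed point and scoring is well defined.
    """
    n_pw = rng.integers(1, 4)
    pathways = [f"PW{i}" for i in range(n_pw)]
    n_l = int(rng.integers(1, max_per_layer + 1))
    n_r = int(rng.integers(1, max_per_layer + 1))
    n_t = int(rng.integers(1, max_per_layer + 1))
    n_g = int(rng.integers(1, max_per_layer + 1))
    ligands = [f"L{i}" for i in range(n_l)]
    receptors = [f"R{i}" for i in range(n_r)]
    tfs = [f"TF{i}" for i in range(n_t)]
    targets = [f"G{i}" for i in range(n_g)]

    lr = set()
    for r in receptors:
        lr.add((str(rng.choice(ligands)), r, str(rng.choice(pathways))))
    for l in ligands:
        if not any(e[0] == l for e in lr):
            lr.add((l, str(rng.choice(receptors)), str(rng.choice(pathways))))
    rtf = set()
    for t in tfs:
        rtf.add((str(rng.choice(receptors)), t))
    for r in receptors:
        if not any(e[0] == r for e in rtf):
            rtf.add((r, str(rng.choice(tfs))))
    tft = set()
    for g in targets:
        tft.add((str(rng.choice(tfs)), g))
    for t in tfs:
        if not any(e[0] == t for e in tft):
            tft.add((t, str(rng.choice(targets))))

    network = MultilayerNetwork(
        receiver="recv",
        senders=["send"],
        ligand_nodes=sorted(ligands),
        receptor_nodes=sorted(receptors),
        tf_nodes=sorted(tfs),
        target_nodes=sorted(targets),
        lr_edges=sorted(lr),
        rtf_edges=sorted(rtf),
        tft_edges=sorted(tft),
    )
    deg = pd.DataFrame(
        {"log2_fc": rng.normal(0, 2, size=n_g)},
        index=pd.Index(targets, name="gene"),
    )
    pathways_present = sorted({pw for _, _, pw in lr})
    return network, deg, pathways_present
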