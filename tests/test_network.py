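"""Multilayer network construction, pruning, layer scoring and ranking."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_db, make_profile
from oracles import layer_scores_oracle, random_network
from toppathways import (
    MultilayerNetwork,
    ValidationError,
    build_multilayer_network,
    rank_pathways,
    score_layers,
)


def deg_table(log2_fcs: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"log2_fc": list(log2_fcs.values()), "fold_change": 2.0 ** np.abs(list(log2_fcs.values()))},
        index=pd.Index(log2_fcs.keys(), name="gene"),
    )


def full_profile(genes, clusters=("DP", "EK"), frac=1.0):
    return make_profile(
        {g: {c: 1.0 for c in clusters} for g in genes},
        {g: {c: frac for c in clusters} for g in genes},
    )


class TestBuildNetwork:
    def test_complete_toy_chain(self):
        db = make_db([("L", "R", "FGF")], [("R", "TF")], [("TF", "G")])
        profile = full_profile(["L", "R", "TF", "G"])
        net = build_multilayer_network(profile, db, deg_table({"G": 1.0}), "DP", ["EK"])
        assert (net.ligand_nodes, net.receptor_nodes) == (["L"], ["R"])
        assert (net.tf_nodes, net.target_nodes) == (["TF"], ["G"])
        assert len(net.lr_edges) + len(net.rtf_edges) + len(net.tft_edges) == 3

    def test_fixed_point_pruning(self):
        # TF2's only target is not a DEG -> TF2 pruned; R2 has no other TF -> pruned,
        # and its only ligand L2 goes with it.
        db = make_db(
            [("L1", "R1", "FGF"), ("L2", "R2", "BMP")],
            [("R1", "TF1"), ("R2", "TF2")],
            [("TF1", "G1"), ("TF2", "G2")],
        )
        profile = full_profile(["L1", "L2", "R1", "R2", "TF1", "TF2", "G1", "G2"])
        net = build_multilayer_network(profile, db, deg_table({"G1": 2.0}), "DP", ["EK"])
        assert net.ligand_nodes == ["L1"]
        assert net.receptor_nodes == ["R1"]
        assert net.tf_nodes == ["TF1"]
        assert net.target_nodes == ["G1"]

    def test_ligand_below_expression_fraction_excluded(self):
        db = make_db(
            [("L1", "R1", "FGF"), ("L2", "R1", "BMP")],
            [("R1", "TF1")],
            [("TF1", "G1")],
        )
        profile = make_profile(
            {g: {"DP": 1.0, "EK": 1.0} for g in ["L1", "L2", "R1", "TF1", "G1"]},
            {
                "L1": {"DP": 0.0, "EK": 0.5},
                "L2": {"DP": 0.0, "EK": 0.05},  # below min_expr_frac in all senders
                "R1": {"DP": 0.5, "EK": 0.0},
                "TF1": {"DP": 0.5, "EK": 0.0},
                "G1": {"DP": 0.5, "EK": 0.5},
            },
        )
        net = build_multilayer_network(profile, db, deg_table({"G1": 1.0}), "DP", ["EK"])
        assert net.ligand_nodes == ["L1"]

    def test_empty_network_diagnoses_layer(self):
        db = make_db([("L", "R", "FGF")], [("R", "TF")], [("TF", "G")])
        profile = full_profile(["L", "R", "TF", "G"])
        with pytest.raises(ValidationError, match="target"):
            build_multilayer_network(profile, db, deg_table({}), "DP", ["EK"])


class TestScoreLayers:
    def test_hand_arithmetic(self):
        # targets |log2FC| {1, 3} -> w {0.25, 0.75}; TF1 -> both (mean 0.5),
        # TF2 -> T2 only (0.75) -> u {0.4, 0.6}
        net = MultilayerNetwork(
            receiver="DP", senders=["EK"],
            ligand_nodes=["L1"], receptor_nodes=["R1"],
            tf_nodes=["TF1", "TF2"], target_nodes=["T1", "T2"],
            lr_edges=[("L1", "R1", "FGF")],
            rtf_edges=[("R1", "TF1"), ("R1", "TF2")],
            tft_edges=[("TF1", "T1"), ("TF1", "T2"), ("TF2", "T2")],
        )
        layers = score_layers(net, deg_table({"T1": 1.0, "T2": -3.0}))
        assert layers.target_w == pytest.approx({"T1": 0.25, "T2": 0.75})
        assert layers.tf_u == pytest.approx({"TF1": 0.4, "TF2": 0.6})
        assert layers.receptor_v == pytest.approx({"R1": 1.0})
        assert layers.ligand_z == pytest.approx({"L1": 1.0})
        assert layers.pathway_score == pytest.approx({"FGF": 1.0})

    def _two_pathway_net(self):
        return MultilayerNetwork(
            receiver="DP", senders=["EK"],
            ligand_nodes=["LA", "LB"], receptor_nodes=["RA", "RB"],
            tf_nodes=["TA", "TB"], target_nodes=["GA", "GB"],
            lr_edges=[("LA", "RA", "A"), ("LB", "RB", "B")],
            rtf_edges=[("RA", "TA"), ("RB", "TB")],
            tft_edges=[("TA", "GA"), ("TB", "GB")],
        )

    def test_symmetric_pathways_split_evenly(self):
        layers = score_layers(self._two_pathway_net(), deg_table({"GA": 2.0, "GB": 2.0}))
        assert layers.pathway_score == pytest.approx({"A": 0.5, "B": 0.5})

    def test_removing_a_pathways_ligand_renormalizes(self):
        net = self._two_pathway_net()
        pruned = MultilayerNetwork(
            receiver=net.receiver, senders=net.senders,
            ligand_nodes=["LB"], receptor_nodes=["RB"], tf_nodes=["TB"], target_nodes=["GB"],
            lr_edges=[("LB", "RB", "B")], rtf_edges=[("RB", "TB")], tft_edges=[("TB", "GB")],
        )
        layers = score_layers(pruned, deg_table({"GB": 2.0}))
        assert layers.pathway_score == pytest.approx({"B": 1.0})

    def test_count_mode_uses_target_multiplicity(self):
        net = MultilayerNetwork(
            receiver="DP", senders=["EK"],
            ligand_nodes=["L1"], receptor_nodes=["R1"],
            tf_nodes=["TF1", "TF2"], target_nodes=["T1", "T2", "T3"],
            lr_edges=[("L1", "R1", "FGF")],
            rtf_edges=[("R1", "TF1"), ("R1", "TF2")],
            tft_edges=[("TF1", "T1"), ("TF1", "T2"), ("TF2", "T3")],
        )
        layers = score_layers(net, deg_table({"T1": 1.0, "T2": 1.0, "T3": 1.0}), tf_mode="count")
        assert layers.tf_u == pytest.approx({"TF1": 2 / 3, "TF2": 1 / 3})

    @pytest.mark.parametrize("seed", range(30))
    def test_layers_sum_to_one_on_random_networks(self, seed):
        net, deg, _ = random_network(np.random.default_rng(seed))
        layers = score_layers(net, deg)
        for mapping in (layers.target_w, layers.tf_u, layers.receptor_v,
                        layers.ligand_z, layers.pathway_score):
            assert sum(mapping.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in mapping.values())

    def test_missing_target_in_deg_is_internal_error(self):
        net = self._two_pathway_net()
        with pytest.raises(ValidationError, match="missing"):
            score_layers(net, deg_table({"GA": 1.0}))


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(100))
    def test_boosting_a_private_target_never_lowers_its_pathway(self, seed):
        rng = np.random.default_rng(seed)
        # two disjoint sub-networks with random sizes; GA0 reachable only from A
        n_a = int(rng.integers(1, 4))
        n_b = int(rng.integers(1, 4))
        tft = [("TA", f"GA{i}") for i in range(n_a)] + [("TB", f"GB{i}") for i in range(n_b)]
        net = MultilayerNetwork(
            receiver="DP", senders=["EK"],
            ligand_nodes=["LA", "LB"], receptor_nodes=["RA", "RB"],
            tf_nodes=["TA", "TB"],
            target_nodes=[g for _, g in tft],
            lr_edges=[("LA", "RA", "A"), ("LB", "RB", "B")],
            rtf_edges=[("RA", "TA"), ("RB", "TB")],
            tft_edges=tft,
        )
        fcs = {g: float(rng.uniform(0.1, 4)) for _, g in tft}
        base = score_layers(net, deg_table(fcs)).pathway_score["A"]
        fcs["GA0"] += float(rng.uniform(0.1, 5))
        boosted = score_layers(net, deg_table(fcs)).pathway_score["A"]
        assert boosted >= base - 1e-12


class TestRankPathways:
    def test_sort_and_ranks(self):
        net, deg, _ = random_network(np.random.default_rng(1))
        layers = score_layers(net, deg)
        activity = rank_pathways(layers)
        assert list(activity.table["rank"]) == list(range(1, len(activity.table) + 1))
        assert activity.table["activity"].is_monotonic_decreasing
        assert activity.table["activity"].sum() == pytest.approx(1.0)

    def test_tie_broken_lexicographically(self):
        from toppathways import LayerScores

        layers = LayerScores({}, {}, {}, {}, {"B": 0.5, "A": 0.5})
        activity = rank_pathways(layers)
        assert list(activity.table["pathway"]) == ["A", "B"]
        assert activity.top_pathway == "A"

    def test_oracle_agreement_single_instance(self):
        net, deg, _ = random_network(np.random.default_rng(9))
        got = score_layers(net, deg).pathway_score
        expected = layer_scores_oracle(net, deg)["P"]
        assert got == pytest.approx(expected, abs=1e-12)
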