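"""Score ligand-receptor interactions between clusters and rank incoming signals.

Builds a tiny two-cluster expression profile by hand: the sender cluster EK
expresses the ligand, the receiver DP expresses the receptor. The raw score
of an ordered cluster pair is the product of the sender's mean ligand and the
receiver's mean receptor expression; each ligand-receptor pair's scores are
normalized to sum to 1 over all ordered cluster pairs.
"""

import pandas as pd

from toppathways import ClusterProfile, PathwayDatabase, count_interactions, \
    interaction_scores, rank_incoming_ligands

mean_expr = pd.DataFrame(
    {"DP": [0.2, 3.0, 0.1], "EK": [4.0, 0.0, 2.5]},
    index=["FGF8", "FGFR1", "BMP4"],
)
profile = ClusterProfile(
    clusters=["DP", "EK"],
    mean_expr=mean_expr,
    expr_frac=mean_expr.clip(upper=1.0),
    n_cells=pd.Series([100, 80], index=["DP", "EK"]),
)
db = PathwayDatabase(
    lr_pairs=pd.DataFrame(
        [("FGF8", "FGFR1", "FGF"), ("BMP4", "FGFR1", "BMP")],
        columns=["ligand", "receptor", "pathway"],
    ),
    receptor_tf=pd.DataFrame(columns=["receptor", "tf"]),
    tf_target=pd.DataFrame(columns=["tf", "target"]),
)

table = interaction_scores(profile, db)
print("all ordered cluster pairs (norm_score sums to 1 per LR pair):")
print(table.to_string(index=False))

ranked = rank_incoming_ligands(table, receiver_cluster="DP")
print("\nincoming signals to the DP progenitor, strongest first:")
print(ranked[["ligand", "receptor", "pathway", "sender", "norm_score", "rank"]]
      .to_string(index=False))

counts = count_interactions(table, receiver_cluster="DP", min_norm=0.5)
print("\ninteractions with norm_score >= 0.5 into DP (chord-diagram widths):")
print(counts.to_string(index=False))
print("\nEK -> DP dominates: the ligands sit in EK and the receptor in DP, "
      "so the autocrine and reverse pairs score near zero.")
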