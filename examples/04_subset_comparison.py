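"""Compare pathway activity between two subsets (incisor vs molar style).

Simulates two subsets in which the planted FGF signaling effect into the DP
progenitor is seven times larger in the incisor than in the molar, runs the
full pipeline independently per subset, and reports per-pathway activity
ratios.
"""

from toppathways import pathway_activity_ratio, run_toppathways
from toppathways.simulate import ratio_config, simulate_dataset

RHO = 7
config = ratio_config(RHO)
ds, db, _ = simulate_dataset(config, seed=0)

incisor = run_toppathways(ds, db, config.default_transition("incisor"))
molar = run_toppathways(ds, db, config.default_transition("molar"))
comparison = pathway_activity_ratio(incisor, molar, labels=("incisor", "molar"))

table = comparison.table.rename(
    columns={"activity_a": "incisor", "activity_b": "molar", "ratio_a_over_b": "ratio"}
)
print(table[["pathway", "incisor", "molar", "ratio"]].round(4).to_string(index=False))
print(f"\nFGF activity ratio incisor/molar: "
      f"{table.set_index('pathway').loc['FGF', 'ratio']:.2f} "
      f"(planted effect ratio {RHO}:1)")
print("Activities are normalized to sum to 1 within each run; the seven "
      "reference pathways respond identically in both subsets, so the FGF "
      "ratio isolates the planted subset difference (compressed toward 1 by "
      "the shared normalization).")
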