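"""Cell-type proportion kinetics, first appearance and developmental scores.

Simulates two tooth-germ subsets across five gestational-week stages where
mature odontoblasts (OB) appear one stage earlier in the incisor than in the
molar, with planted maturation/progenitor marker gradients along
DP -> POB -> OB.
"""

from toppathways import (
    celltype_proportions,
    cluster_dev_scores,
    developmental_score,
    first_appearance,
    normalize_cp10k,
    qc_filter,
)
from toppathways.simulate import kinetics_config, simulate_dataset

config = kinetics_config()
ds, _, truth = simulate_dataset(config, seed=0)

props = celltype_proportions(ds, {c: "tooth" for c in config.clusters})
ob = props[props["cell_type"] == "OB"]
print("OB fraction per (subset, stage):")
print(ob[["subset", "stage", "count", "fraction"]].to_string(index=False))

detected = first_appearance(props, "OB", min_fraction=config.presence_threshold)
print(f"\nfirst stage where OB reaches 1% of the compartment: {detected}")
print(f"planted truth:                                       "
      f"{ {s: truth.first_appearance[s]['OB'] for s in detected} }")

norm = normalize_cp10k(qc_filter(ds))
maturation = [f"MATM{i + 1}" for i in range(config.n_maturation_markers)]
progenitor = [f"PROGM{i + 1}" for i in range(config.n_progenitor_markers)]
dev = cluster_dev_scores(developmental_score(norm, maturation, progenitor))
print("\ncluster-mean developmental score (maturation minus progenitor "
      "module score; higher = more mature):")
print(dev["dev_score"].round(3).to_string())
print("\nThe score rises along the planted odontoblast lineage "
      "DP -> POB -> OB, and the molar lags the incisor by one stage in OB "
      "appearance, mirroring delayed molar maturation kinetics.")
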