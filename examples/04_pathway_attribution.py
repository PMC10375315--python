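"""Ablation-based pathway attribution for one (cell, drug) prediction.

The relative improvement score (RIS) of a term compares the prediction
shift when the term's module is silenced (s_f) against the shift when
all of its children - or, for a leaf, its gene inputs - are silenced
(s_cf): RIS = (s_cf - s_f)/(s_cf + s_f). Positive scores mean the
children carry more signal than the term's own integration.
"""

import numpy as np

from pathvnn.explain import ris_scores
from pathvnn.model import ModelConfig, build_model, train
from pathvnn.synthetic import simulate_preset

layout, cohort, feats, triplets, truth = simulate_preset("tiny", seed=3)
config = ModelConfig(seed=3, epochs=10, learning_rate=1e-3, batch_size=64)
model = build_model(layout, config, feats.width)
model, _ = train(model, cohort, feats, triplets, config)

# pick a drug with a planted mechanism and a cell where it is active
drug = next(d for d, m in truth.mechanism.items() if m)
mech = truth.mechanism[drug]
cell = truth.activity.index[truth.activity[mech].sum(axis=1) == len(mech)][0]

table = ris_scores(model, cohort, feats, cell, drug)
top = table.sort_values("ris", ascending=False).head(5)
print(f"cell {cell}, drug {drug} (planted mechanism: {mech})")
print(top[["term", "s_f", "s_cf", "ris"]].round(4).to_string(index=False))
print("terms with high RIS drive this prediction through their inputs; "
      "the planted mechanism terms should sit near the top of the leaf "
      "ranking once the model has learned the signal.")
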