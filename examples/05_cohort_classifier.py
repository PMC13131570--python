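"""Predict memory outcome from network-remodelling features.

Simulates a 21-animal cohort (7 control, 7 interference-during-consolidation =
forgetting, 7 interference-after-consolidation), assembles the six remodelling
features per animal, and runs the leave-one-out elastic-net logistic
classifier.
"""

import numpy as np

from engramnet import (
    assemble_features,
    compare_sessions,
    loocv_classify,
    simulate_cohort,
)

bundles = simulate_cohort(7, seed=3, sessions=("training", "test"))
reports = {b.animal_id: compare_sessions(b.rasters["training"],
                                         b.rasters["test"], b.regmap)
           for b in bundles}
records = {b.animal_id: b.record for b in bundles}

fm = assemble_features(reports, records)
print(f"feature matrix: {fm.X.shape[0]} animals x {fm.X.shape[1]} features")
print(f"forgetting animals: {int(fm.y.sum())} / {len(fm.y)}")

rep = loocv_classify(fm, l1_ratio=0.5, reg_strength=1.0, seed=3)
print(f"\nLOOCV accuracy: {rep.accuracy:.3f}")
print(f"LOOCV AUC:      {rep.auc:.3f}")
print(f"confusion matrix (rows true remember/forget):\n{rep.confusion}")
worst = np.argsort(np.abs(rep.probabilities - rep.y_true))[-1]
print(f"hardest animal: {rep.animal_ids[worst]} "
      f"(true {'forget' if rep.y_true[worst] else 'remember'}, "
      f"P(forget) = {rep.probabilities[worst]:.2f})")
print("\nAUC is the probability that a randomly chosen forgetting animal "
      "receives a higher predicted forget-probability than a remembering one.")
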