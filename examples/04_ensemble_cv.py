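"""Cross-validated ensemble prediction of shoot and fruit fresh weight.

Four base learners (two gradient-boosted tree variants, a random
forest, a feed-forward network) are combined by greedy weighted
ensembling on their out-of-fold predictions.  Test folds contain only
original records; augmentation, when enabled, is regenerated inside
each training fold.
"""

import numpy as np

from pepperfw import AugmentationConfig, generate_dataset, make_fold_plan, run_cv
from pepperfw.synthetic import SimConfig

data = generate_dataset(SimConfig(seed=42))
plan = make_fold_plan(data, k=5, repeats=1, seed=0)

for target in ("shoot_fw", "fruit_fw"):
    for label, cfg in (("original", None), ("augmented", AugmentationConfig(seed=1))):
        res = run_cv(data, "ensemble", plan, target=target, aug_config=cfg, seed=0)
        w = np.round(res.weights_per_repeat[0], 3)
        print(
            f"{target:9s} {label:9s}  OOF R^2 = {res.r2_mean:.3f}"
            f"  RMSE = {res.rmse_mean:.1f} g  weights(lgbm,xgb,rf,ffnn) = {w}"
        )
print(
    "\nR^2 close to 1 and RMSE in grams of fresh weight; the ensemble's"
    " OOF RMSE never exceeds the best single base learner's."
)
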