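"""Feature-group ablation and permutation-sampling Shapley attribution.

Two complementary views of what drives the fresh-weight predictions:

* **Ablation** removes one named feature group (basic, structural,
  temporal, management), re-runs the full cross-validated ensemble
  pipeline (augmentation included) under the identical fold plan, and
  reports the drop in OOF R^2 relative to the full model.  The drop may
  be negative — removing a group can help.

* **Shapley attribution** explains individual predictions of a fitted
  model: for each observation, features are switched one by one from a
  background row's values to the observation's values along random
  feature orderings, and the marginal prediction changes are averaged.
  The estimator satisfies efficiency by construction: the per-
  observation baseline (mean model output over the sampled background
  rows) plus the summed attributions equals the model's prediction.
  With ``exhaustive=True`` all d! orderings are enumerated (exact
  Shapley values; practical for d <= 8).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import AugmentationConfig
from .evaluation import FoldPlan, run_cv
from .learners import FEATURE_GROUPS

__all__ = [
    "ablate_group",
    "ablation_table",
    "shapley_attribution",
    "AttributionResult",
    "importance_report",
]


def ablate_group(
    records: pd.DataFrame,
    group: str,
    plan: FoldPlan,
    target: str,
    aug_config: AugmentationConfig | None = None,
    full_r2: float | None = None,
    seed: int = 0,
) -> dict:
    """Retrain the ensemble without one feature group; report delta R^2."""
    if group not in FEATURE_GROUPS:
        raise ValueError(f"unknown feature group {group!r}; allowed: {list(FEATURE_GROUPS)}")
    kept = tuple(g for g in FEATURE_GROUPS if g != group)
    if not kept:
        raise ValueError("removing this group leaves zero features")
    if full_r2 is None:
        full = run_cv(records, "ensemble", plan, target=target,
                      aug_config=aug_config, seed=seed)
        full_r2 = full.r2_mean
    reduced = run_cv(records, "ensemble", plan, target=target,
                     aug_config=aug_config, feature_groups=kept, seed=seed)
    return {
        "group": group,
        "target": target,
        "r2_full": float(full_r2),
        "r2_reduced": reduced.r2_mean,
        "delta_r2": float(full_r2) - reduced.r2_mean,
    }


def ablation_table(
    records: pd.DataFrame,
    plan: FoldPlan,
    targets: tuple[str, ...] = ("shoot_fw", "fruit_fw"),
    aug_config: AugmentationConfig | None = None,
    groups: tuple[str, ...] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Delta R^2 for every feature group x target (full model fit once per target)."""
    groups = tuple(groups) if groups is not None else tuple(FEATURE_GROUPS)
    rows = []
    for target in targets:
        full = run_cv(records, "ensemble", plan, target=target,
                      aug_config=aug_config, seed=seed)
        for g in groups:
            rows.append(
                ablate_group(records, g, plan, target, aug_config=aug_config,
                             full_r2=full.r2_mean, seed=seed)
            )
    return pd.DataFrame(rows)


@dataclass
class AttributionResult:
    """Per-observation, per-feature Shapley values (g of fresh weight)."""

    values: np.ndarray  # (n_obs, d)
    baseline: np.ndarray  # (n_obs,) expected prediction over background draws
    predictions: np.ndarray  # (n_obs,) model output at the explained points
    feature_names: list[str]
    X_explain: np.ndarray
    settings: dict = field(default_factory=dict)

    def mean_abs(self) -> pd.Series:
        """Mean |attribution| per feature, for importance ranking."""
        s = pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names)
        return s.sort_values(ascending=False)

    def grouped_mean_abs(self) -> pd.Series:
        """Like :meth:`mean_abs` but with one-hot treatment columns summed
        back into a single ``treatment`` factor."""
        vals = pd.DataFrame(self.values, columns=self.feature_names)
        trt = [c for c in vals.columns if c.startswith("treatment_")]
        if trt:
            vals["treatment"] = vals[trt].sum(axis=1)
            vals = vals.drop(columns=trt)
        return vals.abs().mean(axis=0).sort_values(ascending=False)


def shapley_attribution(
    predict_fn,
    X_explain: np.ndarray,
    X_background: np.ndarray,
    feature_names: list[str] | None = None,
    n_permutations: int = 200,
    seed: int = 0,
    exhaustive: bool = False,
) -> AttributionResult:
    """Permutation-sampling Shapley values for a regression model.

    For each explained row x and each draw (a feature ordering plus a
    background row b), the prediction is tracked as features flip from
    b's values to x's values in the ordering; the change at each flip is
    credited to that feature.  Attributions are the means over draws.
    ``exhaustive=True`` enumerates every ordering crossed with every
    background row (exact for interventional Shapley with that
    background); otherwise ``n_permutations`` orderings are sampled,
    each paired with one uniformly drawn background row.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
    if len(X_background) == 0:
        raise ValueError("background set must be non-empty")
    n_obs, d = X_explain.shape
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)

    if exhaustive:
        perms = np.array(list(itertools.permutations(range(d))), dtype=int)
        bg_idx = np.repeat(np.arange(len(X_background)), len(perms))
        perms = np.tile(perms, (len(X_background), 1))
    else:
        perms = np.array([rng.permutation(d) for _ in range(n_permutations)])
        bg_idx = rng.integers(0, len(X_background), size=n_permutations)
    n_draws = len(perms)

    values = np.zeros((n_obs, d))
    baseline = np.zeros(n_obs)
    preds = np.asarray(predict_fn(X_explain), dtype=float)
    for i in range(n_obs):
        x = X_explain[i]
        # coalition matrix: for each draw, d+1 states from background to x
        states = np.empty((n_draws, d + 1, d))
        states[:, 0, :] = X_background[bg_idx]
        for step in range(d):
            states[:, step + 1, :] = states[:, step, :]
            rows = np.arange(n_draws)
            states[rows, step + 1, perms[:, step]] = x[perms[:, step]]
        out = np.asarray(predict_fn(states.reshape(-1, d)), dtype=float)
        out = out.reshape(n_draws, d + 1)
        marginal = np.diff(out, axis=1)  # (n_draws, d) credit per step
        contrib = np.zeros(d)
        np.add.at(contrib, perms.ravel(), marginal.ravel())
        values[i] = contrib / n_draws
        baseline[i] = out[:, 0].mean()
    return AttributionResult(
        values=values,
        baseline=baseline,
        predictions=preds,
        feature_names=list(feature_names) if feature_names else [f"x{j}" for j in range(d)],
        X_explain=X_explain,
        settings={
            "n_permutations": None if exhaustive else n_permutations,
            "exhaustive": exhaustive,
            "background_size": int(len(X_background)),
            "seed": seed,
        },
    )


def importance_report(
    ablation: pd.DataFrame | None = None,
    attribution: AttributionResult | None = None,
) -> dict:
    """Machine-readable importance report combining both analyses.

    Sections are included for whichever inputs are provided; an absent
    attribution (or ablation) is flagged rather than an error.
    """
    report: dict = {"flags": []}
    if ablation is not None and len(ablation):
        report["ablation"] = {
            target: {
                row["group"]: {
                    "r2_full": row["r2_full"],
                    "r2_reduced": row["r2_reduced"],
                    "delta_r2": row["delta_r2"],
                }
                for _, row in sub.iterrows()
            }
            for target, sub in ablation.groupby("target")
        }
    else:
        report["flags"].append("ablation section missing")
    if attribution is not None:
        ranking = attribution.grouped_mean_abs()
        report["attribution"] = {
            "mean_abs": ranking.to_dict(),
            "ranking": list(ranking.index),
            "beeswarm": {
                "values": attribution.values.tolist(),
                "feature_values": attribution.X_explain.tolist(),
                "features": attribution.feature_names,
            },
            "settings": attribution.settings,
        }
    else:
        report["flags"].append("attribution section missing")
    return report
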