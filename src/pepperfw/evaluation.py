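"""Leakage-safe repeated K-fold cross-validation and metrics.

The fold plan (5 folds x 3 repeats by default) is defined over the
ORIGINAL records only: test folds contain exclusively measured plants,
and when augmentation is enabled the synthetic rows are regenerated per
training fold from that fold's training originals alone, so no
information about a test plant can reach the model through a synthetic
row.  Both constraints are asserted on every fold at run time.

Out-of-fold (OOF) predictions — each record predicted by a model never
trained on it — are assembled per repeat and summarized as R^2 and RMSE
with mean +/- sd across repeats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import AugmentationConfig, augment_dataset
from .learners import (
    BASE_KINDS,
    feature_matrix,
    fit_ensemble_weights,
    train_base,
)
from .records import GROUP_KEYS, originals

__all__ = ["FoldPlan", "make_fold_plan", "r2", "rmse", "run_cv", "CVResult"]


def r2(y, yhat) -> float:
    """Coefficient of determination, 1 - SSE/SST with SST about mean(y)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) == 0 or len(y) != len(yhat):
        raise ValueError("r2 requires equal nonzero lengths")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: target has zero variance")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) == 0 or len(y) != len(yhat):
        raise ValueError("rmse requires equal nonzero lengths")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class FoldPlan:
    """Repeated K-fold assignment over the original records.

    ``assignments[r, i]`` is the test-fold index of original record i
    in repeat r.  Serializable to JSON; identical on replay for the
    same seed.
    """

    k: int
    repeats: int
    seed: int
    assignments: np.ndarray  # (repeats, n) int

    @property
    def n(self) -> int:
        return self.assignments.shape[1]

    def split(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train positions, test positions) within the original records."""
        a = self.assignments[repeat]
        test = np.flatnonzero(a == fold)
        train = np.flatnonzero(a != fold)
        return train, test

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "repeats": self.repeats,
                "seed": self.seed,
                "assignments": self.assignments.tolist(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "FoldPlan":
        d = json.loads(s)
        return cls(
            k=d["k"],
            repeats=d["repeats"],
            seed=d["seed"],
            assignments=np.asarray(d["assignments"], dtype=int),
        )


def make_fold_plan(records: pd.DataFrame, k: int = 5, repeats: int = 3,
                   seed: int = 0) -> FoldPlan:
    """Seeded, (season, treatment)-stratified repeated K-fold plan.

    Synthetic rows are ignored.  Within each repeat, records are
    shuffled within each (season, treatment) stratum, concatenated, and
    dealt round-robin to folds: fold sizes differ by at most one while
    strata spread across folds.
    """
    orig = originals(records).reset_index(drop=True)
    n = len(orig)
    if n < k:
        raise ValueError(f"need at least k={k} original records, got {n}")
    strata = orig.groupby(["season", "treatment"], sort=True).indices
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        order = np.concatenate(
            [rng.permutation(np.asarray(idx)) for _, idx in sorted(strata.items())]
        )
        fold_cycle = rng.permutation(k)
        for pos, rec_idx in enumerate(order):
            assignments[r, rec_idx] = fold_cycle[pos % k]
    return FoldPlan(k=k, repeats=repeats, seed=seed, assignments=assignments)


class LeakageError(AssertionError):
    """A synthetic or test-fold row violated the leakage-safety rules."""


@dataclass
class CVResult:
    """Per-repeat OOF metrics plus the assembled OOF predictions."""

    model: str
    target: str
    r2_per_repeat: list[float]
    rmse_per_repeat: list[float]
    oof: np.ndarray  # (repeats, n)
    fold_log: list[dict] = field(default_factory=list)
    base_oof: dict[str, np.ndarray] = field(default_factory=dict)  # ensemble only
    weights_per_repeat: list[np.ndarray] = field(default_factory=list)
    base_rmse_per_repeat: list[dict] = field(default_factory=list)

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_per_repeat))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.r2_per_repeat, ddof=1)) if len(self.r2_per_repeat) > 1 else 0.0

    @property
    def rmse_mean(self) -> float:
        return float(np.mean(self.rmse_per_repeat))


def _fold_seed(seed: int, repeat: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, repeat, fold]).generate_state(1)[0] % (2**31))


def _check_leakage(train_orig: pd.DataFrame, train_aug: pd.DataFrame,
                   test_rows: pd.DataFrame) -> dict:
    """Assert the two leakage-safety rules for one fold; return a log entry."""
    if test_rows["is_synthetic"].any():
        raise LeakageError("synthetic row found in a test fold")
    synth = train_aug.loc[train_aug["is_synthetic"].astype(bool)]
    train_keys = {
        (s, t, int(d))
        for s, t, d in train_orig[list(GROUP_KEYS)].itertuples(index=False)
    }
    for sg in synth["source_group"].unique():
        season, treatment, dat = sg.split("|")
        if (season, treatment, int(dat)) not in train_keys:
            raise LeakageError(
                f"synthetic row sourced from group {sg!r} outside the training originals"
            )
    return {
        "n_train_orig": int(len(train_orig)),
        "n_train_synth": int(len(synth)),
        "n_test": int(len(test_rows)),
        "leakage_ok": True,
    }


def run_cv(
    records: pd.DataFrame,
    model: str,
    plan: FoldPlan,
    target: str = "shoot_fw",
    aug_config: AugmentationConfig | None = None,
    feature_groups: tuple[str, ...] | None = None,
    base_kinds: tuple[str, ...] = BASE_KINDS,
    seed: int = 0,
) -> CVResult:
    """Run one model family through the fold plan.

    ``model`` is ``"ensemble"``, one of the base-learner kinds, or the
    diagnostic families ``"mean"`` (training-mean predictor) and
    ``"oracle"`` (predicts the true target).  ``aug_config`` enables
    per-training-fold augmentation (synthetic rows generated from the
    fold's training originals only); the fold plan itself never changes
    with augmentation.
    """
    orig = originals(records).reset_index(drop=True)
    if plan.n != len(orig):
        raise ValueError(f"fold plan covers {plan.n} records but data has {len(orig)}")
    y = orig[target].to_numpy(dtype=float)

    oof = np.full((plan.repeats, len(orig)), np.nan)
    base_oof = {b: np.full((plan.repeats, len(orig)), np.nan) for b in base_kinds} \
        if model == "ensemble" else {}
    fold_log: list[dict] = []
    weights_per_repeat: list[np.ndarray] = []
    base_rmse_per_repeat: list[dict] = []
    r2s, rmses = [], []

    for rep in range(plan.repeats):
        for fold in range(plan.k):
            train_idx, test_idx = plan.split(rep, fold)
            train_orig = orig.iloc[train_idx]
            test_rows = orig.iloc[test_idx]

            if aug_config is not None:
                fold_cfg = AugmentationConfig(
                    n_thr=aug_config.n_thr,
                    noise_scale=aug_config.noise_scale,
                    factor=aug_config.factor,
                    vae=aug_config.vae,
                    perturb_targets=aug_config.perturb_targets,
                    seed=_fold_seed(aug_config.seed, rep, fold),
                )
                train_all, _ = augment_dataset(train_orig, fold_cfg)
            else:
                train_all = train_orig
            fold_log.append(_check_leakage(train_orig, train_all, test_rows))

            if model == "oracle":
                oof[rep, test_idx] = test_rows[target].to_numpy(dtype=float)
                continue
            if model == "mean":
                oof[rep, test_idx] = float(train_orig[target].mean())
                continue

            X_tr, names = feature_matrix(train_all, feature_groups)
            y_tr = train_all[target].to_numpy(dtype=float)
            X_te, _ = feature_matrix(test_rows, feature_groups)

            # inner validation split (original rows only) for FFNN early stopping
            frng = np.random.default_rng(_fold_seed(seed, rep, fold) ^ 0x5EED)
            n_tr_orig = len(train_orig)
            perm = frng.permutation(n_tr_orig)
            n_val = max(1, n_tr_orig // 5)
            val_pos, keep_pos = perm[:n_val], perm[n_val:]
            X_val, _ = feature_matrix(train_orig.iloc[val_pos], feature_groups)
            y_val = train_orig.iloc[val_pos][target].to_numpy(dtype=float)

            kinds = base_kinds if model == "ensemble" else (model,)
            for kind in kinds:
                if kind == "ffnn":
                    # exclude the inner validation originals from FFNN training
                    mask = np.ones(len(train_all), dtype=bool)
                    mask[val_pos] = False  # originals come first in train_all
                    m = train_base(
                        kind, X_tr[mask], y_tr[mask], X_val, y_val,
                        seed=_fold_seed(seed, rep, fold),
                    )
                else:
                    m = train_base(kind, X_tr, y_tr, seed=_fold_seed(seed, rep, fold))
                pred = np.asarray(m.predict(X_te), dtype=float)
                if model == "ensemble":
                    base_oof[kind][rep, test_idx] = pred
                else:
                    oof[rep, test_idx] = pred

        if model == "ensemble":
            P = np.column_stack([base_oof[b][rep] for b in base_kinds])
            w = fit_ensemble_weights(P, y)
            weights_per_repeat.append(w)
            oof[rep] = P @ w
            base_rmse_per_repeat.append(
                {b: rmse(y, base_oof[b][rep]) for b in base_kinds}
            )
        r2s.append(r2(y, oof[rep]))
        rmses.append(rmse(y, oof[rep]))

    return CVResult(
        model=model,
        target=target,
        r2_per_repeat=r2s,
        rmse_per_repeat=rmses,
        oof=oof,
        fold_log=fold_log,
        base_oof=base_oof,
        weights_per_repeat=weights_per_repeat,
        base_rmse_per_repeat=base_rmse_per_repeat,
    )


def fit_ensemble_model(
    records: pd.DataFrame,
    plan: FoldPlan,
    target: str = "shoot_fw",
    aug_config: AugmentationConfig | None = None,
    feature_groups: tuple[str, ...] | None = None,
    base_kinds: tuple[str, ...] = BASE_KINDS,
    seed: int = 0,
):
    """Fit a deployable ensemble: CV for the weights, then refit on all data.

    Base weights come from greedy selection on the OOF predictions
    pooled across repeats; the base learners are then retrained on the
    full (optionally augmented) dataset.
    """
    from .learners import EnsembleModel

    cv = run_cv(records, "ensemble", plan, target=target, aug_config=aug_config,
                feature_groups=feature_groups, base_kinds=base_kinds, seed=seed)
    orig = originals(records).reset_index(drop=True)
    y = orig[target].to_numpy(dtype=float)
    P = np.vstack([
        np.column_stack([cv.base_oof[b][rep] for b in base_kinds])
        for rep in range(plan.repeats)
    ])
    w = fit_ensemble_weights(P, np.tile(y, plan.repeats))

    train_all = records
    if aug_config is not None:
        train_all, _ = augment_dataset(orig, aug_config)
    X, names = feature_matrix(train_all, feature_groups)
    yt = train_all[target].to_numpy(dtype=float)
    models = []
    for kind in base_kinds:
        models.append(train_base(kind, X, yt, seed=seed))
    oof_rmse = {b: float(rmse(np.tile(y, plan.repeats), P[:, i]))
                for i, b in enumerate(base_kinds)}
    oof_rmse["ensemble"] = float(rmse(np.tile(y, plan.repeats), P @ w))
    return EnsembleModel(kinds=tuple(base_kinds), models=models, weights=w,
                         feature_names=names, oof_rmse=oof_rmse), cv
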