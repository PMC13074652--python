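"""Base regressors and the simplex-constrained weighted ensemble.

Four base learners mirror the four-model stacked ensemble of the study:
two gradient-boosted tree regressors with different leaf-growth
strategies (LightGBM, leaf-wise; XGBoost, depth-wise), a random forest,
and a small feed-forward neural network (two hidden layers of 32 and 8
units with batch normalization, ReLU and dropout, Adam on mean squared
error, at most 500 epochs with early stopping after 80 non-improving
validation epochs).

The ensemble is a convex combination of the base predictions.  Weights
are found by greedy ensemble selection with replacement on the
out-of-fold (validation) predictions: starting from the empty ensemble,
the base model whose inclusion minimizes the RMSE of the running
average is added for a fixed number of rounds, and the weights are the
selection frequencies at the best round.  This guarantees non-negative
weights summing to one and an ensemble OOF RMSE no worse than the best
single base model (the best single model is itself a feasible pick).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Adam, BatchNorm, Dense, Dropout, ReLU, Sequential, minibatches

# lightgbm's sklearn wrapper records feature names even for plain arrays,
# making every ndarray predict() emit this warning; it is meaningless here
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)

__all__ = [
    "FEATURE_GROUPS",
    "BASE_KINDS",
    "feature_matrix",
    "FFNNConfig",
    "FFNNRegressor",
    "train_base",
    "fit_ensemble_weights",
    "EnsembleModel",
    "predict_ensemble",
]

#: The four feature groups used for ablation and model inputs.
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "basic": ("plant_height", "basal_stem_diam"),
    "structural": (
        "main_stem_diam",
        "left_stem_diam",
        "right_stem_diam",
        "main_stem_len",
        "left_stem_len",
        "right_stem_len",
    ),
    "temporal": ("dat",),
    "management": ("treatment", "pruning"),
}

#: Declared base-learner order (ties in greedy selection break this way).
BASE_KINDS = ("lgbm", "xgb", "rf", "ffnn")

_TREATMENT_LEVELS = ("CT", "RB", "FR")


def feature_matrix(
    records: pd.DataFrame, groups: tuple[str, ...] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Build the model input matrix from a record table.

    ``groups`` selects feature groups (default: all four).  Treatment is
    one-hot encoded over the fixed level set so columns are identical
    across folds; pruning is already 0/1.  Returns (X, feature names).
    """
    groups = tuple(groups) if groups is not None else tuple(FEATURE_GROUPS)
    unknown = set(groups) - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature group(s) {sorted(unknown)}")
    cols: list[np.ndarray] = []
    names: list[str] = []
    for g in groups:
        for feat in FEATURE_GROUPS[g]:
            if feat == "treatment":
                for lvl in _TREATMENT_LEVELS:
                    cols.append((records["treatment"] == lvl).to_numpy(dtype=float))
                    names.append(f"treatment_{lvl}")
            else:
                cols.append(records[feat].to_numpy(dtype=float))
                names.append(feat)
    if not names:
        raise ValueError("feature selection left zero input columns")
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("non-finite value in feature matrix")
    return X, names


@dataclass(frozen=True)
class FFNNConfig:
    """Feed-forward network hyperparameters."""

    hidden: tuple[int, int] = (32, 8)
    dropout: float = 0.1
    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 80
    batch_size: int = 64

    def validate(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if min(self.hidden) <= 0 or self.batch_size <= 0:
            raise ValueError("hidden sizes and batch size must be positive")


class FFNNRegressor:
    """Two-hidden-layer regression network with early stopping.

    Features and target are z-scored with training statistics.  When a
    validation set is given, training stops after ``patience`` epochs
    without validation-loss improvement and the best weights are
    restored; ``stopped_epoch_`` records the epoch count actually run.
    """

    def __init__(self, config: FFNNConfig | None = None, seed: int = 0):
        self.config = config or FFNNConfig()
        self.config.validate()
        self.seed = seed
        self.net: Sequential | None = None
        self.stopped_epoch_: int | None = None

    def fit(self, X, y, X_val=None, y_val=None):
        cfg = self.config
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._x_mean = X.mean(axis=0)
        self._x_sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self._y_mean = float(y.mean())
        y_sd = float(y.std())
        if y_sd == 0.0:  # degenerate constant target
            self._y_sd = 0.0
            self.net = None
            self.stopped_epoch_ = 0
            return self
        self._y_sd = y_sd
        Xs = (X - self._x_mean) / self._x_sd
        ys = (y - self._y_mean) / y_sd

        h1, h2 = cfg.hidden
        d = X.shape[1]
        net = Sequential(
            [
                Dense(d, h1, rng), BatchNorm(h1), ReLU(), Dropout(cfg.dropout, rng),
                Dense(h1, h2, rng), BatchNorm(h2), ReLU(), Dropout(cfg.dropout, rng),
                Dense(h2, 1, rng),
            ]
        )
        opt = Adam(net.params, lr=cfg.learning_rate)

        use_val = X_val is not None and y_val is not None and len(np.asarray(y_val)) > 0
        if use_val:
            Xv = (np.asarray(X_val, dtype=float) - self._x_mean) / self._x_sd
            yv = (np.asarray(y_val, dtype=float) - self._y_mean) / y_sd
        best_val, best_state, since_best = np.inf, None, 0
        n = len(Xs)
        epoch = 0
        for epoch in range(1, cfg.max_epochs + 1):
            for idx in minibatches(n, cfg.batch_size, rng):
                out = net.forward(Xs[idx], train=True)
                diff = out - ys[idx, None]
                net.backward(2.0 * diff / diff.size)
                opt.step(net.grads)
            if use_val:
                pv = net.forward(Xv, train=False)[:, 0]
                val = float(np.mean((pv - yv) ** 2))
                if val < best_val - 1e-12:
                    best_val, since_best = val, 0
                    best_state = [p.copy() for p in net.params]
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
        if use_val and best_state is not None:
            for p, b in zip(net.params, best_state):
                p[...] = b
        # re-estimate batch-norm statistics with one full clean pass: the
        # running averages lag the (possibly restored) final weights
        h = Xs
        for lay in net.layers:
            if isinstance(lay, BatchNorm):
                lay.running_mean = h.mean(axis=0)
                lay.running_var = h.var(axis=0)
            h = lay.forward(h, train=False)
        self.net = net
        self.stopped_epoch_ = epoch
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self._y_sd == 0.0 or self.net is None:
            return np.full(len(X), self._y_mean)
        Xs = (X - self._x_mean) / self._x_sd
        return self.net.forward(Xs, train=False)[:, 0] * self._y_sd + self._y_mean


# documented defaults for the hyperparameters the study does not print
_TREE_DEFAULTS = {
    "lgbm": dict(n_estimators=200, learning_rate=0.05, num_leaves=31, min_child_samples=5),
    "xgb": dict(n_estimators=200, learning_rate=0.05, max_depth=6),
    "rf": dict(n_estimators=200),
}


def train_base(kind: str, X, y, X_val=None, y_val=None, seed: int = 0,
               ffnn_config: FFNNConfig | None = None):
    """Train one base learner; returns an object exposing ``predict``.

    ``X_val`` / ``y_val`` drive the FFNN's early stopping and are
    ignored by the tree models.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("NaN or inf in features")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if kind == "lgbm":
        from lightgbm import LGBMRegressor

        model = LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **_TREE_DEFAULTS["lgbm"])
        return model.fit(X, y)
    if kind == "xgb":
        from xgboost import XGBRegressor

        model = XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0, tree_method="hist",
            **_TREE_DEFAULTS["xgb"],
        )
        return model.fit(X, y)
    if kind == "rf":
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(random_state=seed, n_jobs=1, **_TREE_DEFAULTS["rf"])
        return model.fit(X, y)
    if kind == "ffnn":
        if X_val is None or y_val is None:
            # standalone use: last 20% of a seeded shuffle as validation
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(X))
            n_val = max(1, len(X) // 5)
            val_idx, tr_idx = perm[-n_val:], perm[:-n_val]
            X, X_val, y, y_val = X[tr_idx], X[val_idx], y[tr_idx], y[val_idx]
        return FFNNRegressor(ffnn_config, seed=seed).fit(X, y, X_val, y_val)
    raise ValueError(f"unknown base learner kind {kind!r}; allowed: {list(BASE_KINDS)}")


def _rmse(y, p):
    return float(np.sqrt(np.mean((np.asarray(p) - np.asarray(y)) ** 2)))


def fit_ensemble_weights(oof_predictions: np.ndarray, y: np.ndarray,
                         rounds: int = 100) -> np.ndarray:
    """Greedy ensemble selection with replacement on OOF predictions.

    ``oof_predictions`` is (n, m): one column of validation-fold
    predictions per base model.  Each of the fixed 100 rounds adds the
    model minimizing the RMSE of the running average (ties to the
    lowest column index, i.e. the declared base order); the returned
    weights are the selection frequencies at the best round seen, so
    the weighted ensemble's RMSE on these predictions never exceeds the
    best single model's.
    """
    P = np.asarray(oof_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if P.ndim != 2 or P.shape[1] < 1:
        raise ValueError("need an (n, m) prediction matrix with m >= 1")
    if len(y) != P.shape[0]:
        raise ValueError("prediction/target length mismatch")
    n, m = P.shape
    counts = np.zeros(m, dtype=int)
    running = np.zeros(n)
    best_rmse, best_counts = np.inf, None
    for r in range(rounds):
        k = counts.sum()
        cand = np.sqrt(np.mean(((running[:, None] + P) / (k + 1) - y[:, None]) ** 2, axis=0))
        j = int(np.argmin(cand))
        counts[j] += 1
        running += P[:, j]
        if cand[j] < best_rmse:
            best_rmse, best_counts = float(cand[j]), counts.copy()
    w = best_counts / best_counts.sum()
    return w


@dataclass
class EnsembleModel:
    """Fitted base learners plus simplex weights and OOF diagnostics."""

    kinds: tuple[str, ...]
    models: list
    weights: np.ndarray
    feature_names: list[str]
    oof_rmse: dict[str, float] = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_ensemble(self, X)


def predict_ensemble(model: EnsembleModel, X) -> np.ndarray:
    """Convex combination of the base predictions."""
    if not model.models:
        raise ValueError("ensemble has no fitted base models")
    X = np.asarray(X, dtype=float)
    preds = np.column_stack([np.asarray(m.predict(X), dtype=float) for m in model.models])
    return preds @ model.weights


def simplex_grid_weights(P: np.ndarray, y: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Exhaustive simplex grid search over two-model weightings.

    Independent cross-check of the greedy optimizer for m = 2 (used in
    tests); returns the grid-optimal weight vector.
    """
    P = np.asarray(P, dtype=float)
    if P.shape[1] != 2:
        raise ValueError("grid cross-check implemented for exactly 2 models")
    ws = np.arange(0.0, 1.0 + step / 2, step)
    best_w, best = None, np.inf
    for w in ws:
        r = _rmse(y, w * P[:, 0] + (1 - w) * P[:, 1])
        if r < best:
            best, best_w = r, np.array([w, 1 - w])
    return best_w
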