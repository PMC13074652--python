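"""Shapley estimator properties (efficiency, symmetry, dummy, closed form)
and feature-group ablation behavior."""

import itertools

import numpy as np
import pytest

from pepperfw.augmentation import AugmentationConfig
from pepperfw.evaluation import make_fold_plan
from pepperfw.interpretation import (
    ablate_group,
    ablation_table,
    importance_report,
    shapley_attribution,
)
from pepperfw.synthetic import DesignRow, SimConfig, generate_dataset
from pepperfw.vae import VAEConfig


def exact_shapley_enumeration(f, x, background_row):
    """Independent oracle: Shapley values by direct subset enumeration."""
    d = len(x)
    import math

    values = np.zeros(d)
    idx = list(range(d))
    for j in idx:
        others = [i for i in idx if i != j]
        for r in range(d):
            for S in itertools.combinations(others, r):
                w = math.factorial(len(S)) * math.factorial(d - len(S) - 1) / math.factorial(d)
                with_j = background_row.copy()
                with_j[list(S) + [j]] = x[list(S) + [j]]
                without_j = background_row.copy()
                without_j[list(S)] = x[list(S)]
                values[j] += w * (f(with_j[None, :])[0] - f(without_j[None, :])[0])
    return values


class TestShapley:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.W = np.array([2.0, 3.0, -1.0, 0.5])
        self.f = lambda X: np.atleast_2d(X) @ self.W
        self.bg = rng.normal(size=(40, 4))
        self.x = rng.normal(size=(3, 4))

    def test_additive_model_closed_form(self):
        """For f(x) = sum w_j x_j with an independent background, the Shapley
        value of feature j converges to w_j (x_j - mean background_j)."""
        res = shapley_attribution(self.f, self.x, self.bg, n_permutations=2000, seed=1)
        expected = self.W * (self.x - self.bg.mean(axis=0))
        scale = np.abs(expected).max()
        assert np.allclose(res.values, expected, atol=0.02 * scale)

    def test_efficiency_exact_by_construction(self):
        res = shapley_attribution(self.f, self.x, self.bg, n_permutations=50, seed=2)
        recon = res.baseline + res.values.sum(axis=1)
        assert np.allclose(recon, res.predictions, rtol=1e-10)

    def test_exhaustive_matches_subset_enumeration_oracle(self):
        """All-orderings mode equals the direct subset-enumeration formula on
        a nonlinear model with <= 8 features, and efficiency is exact."""
        f = lambda X: np.atleast_2d(X)[:, 0] * np.atleast_2d(X)[:, 1] + np.sin(
            np.atleast_2d(X)[:, 2]
        )
        rng = np.random.default_rng(3)
        x = rng.normal(size=4)
        bg = rng.normal(size=(1, 4))
        res = shapley_attribution(f, x[None, :], bg, exhaustive=True)
        oracle = exact_shapley_enumeration(f, x, bg[0].copy())
        assert np.allclose(res.values[0], oracle, atol=1e-10)
        assert np.isclose(res.baseline[0] + res.values[0].sum(), f(x[None, :])[0])

    def test_sampled_estimator_near_exhaustive(self):
        f = lambda X: np.atleast_2d(X)[:, 0] * np.atleast_2d(X)[:, 1]
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 4)) + 2
        bg = rng.normal(size=(1, 4))
        exact = shapley_attribution(f, x, bg, exhaustive=True)
        approx = shapley_attribution(f, x, bg, n_permutations=2000, seed=5)
        scale = max(np.abs(exact.values).max(), 1e-9)
        assert np.allclose(approx.values, exact.values, atol=0.02 * scale + 0.02)

    def test_observation_equal_to_background_gets_zero(self):
        res = shapley_attribution(self.f, self.bg[:1], self.bg[:1], n_permutations=20, seed=6)
        assert np.allclose(res.values, 0.0)

    def test_symmetry_for_duplicated_features(self):
        """Two features entering the model identically receive equal
        attributions (within Monte-Carlo tolerance)."""
        f = lambda X: np.atleast_2d(X)[:, 0] + np.atleast_2d(X)[:, 1]
        rng = np.random.default_rng(7)
        v = rng.normal(size=(200, 1))
        bg = np.hstack([v, v])  # feature columns identical
        x = np.array([[1.7, 1.7]])
        res = shapley_attribution(f, x, bg, n_permutations=1000, seed=8)
        assert np.isclose(res.values[0, 0], res.values[0, 1], atol=0.05)

    def test_dummy_feature_gets_zero(self):
        f = lambda X: 5.0 * np.atleast_2d(X)[:, 1]
        rng = np.random.default_rng(9)
        bg = rng.normal(size=(30, 3))
        x = rng.normal(size=(2, 3))
        res = shapley_attribution(f, x, bg, n_permutations=200, seed=10)
        assert np.allclose(res.values[:, 0], 0.0, atol=1e-10)
        assert np.allclose(res.values[:, 2], 0.0, atol=1e-10)

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="background"):
            shapley_attribution(self.f, self.x, np.empty((0, 4)))
        with pytest.raises(ValueError, match="n_permutations"):
            shapley_attribution(self.f, self.x, self.bg, n_permutations=0)


def _fast_cfg():
    return AugmentationConfig(seed=0, vae=VAEConfig(epochs=30))


@pytest.fixture(scope="module")
def ablation_dataset():
    """Fruit FW driven purely by DAT (structural/management weights off)."""
    rows = tuple(
        DesignRow(2021, "spring", "M", trt, dat, 10)
        for trt in ("CT", "FR")
        for dat in (40, 70, 100, 130, 150)
    )
    cfg = SimConfig(
        design=rows, seed=5, structural_weight=0.0,
        treatment_fruit_effect={"CT": 1.0, "RB": 1.0, "FR": 1.0},
    )
    return generate_dataset(cfg)


class TestAblation:
    def test_unknown_group_rejected(self, small_dataset):
        plan = make_fold_plan(small_dataset, 5, 1, seed=0)
        with pytest.raises(ValueError, match="unknown feature group"):
            ablate_group(small_dataset, "weather", plan, "shoot_fw")

    def test_temporal_dominates_pure_dat_fruit(self, ablation_dataset):
        """When fruit FW is a function of DAT alone (+noise), removing the
        temporal group causes the largest R^2 drop."""
        plan = make_fold_plan(ablation_dataset, 5, 1, seed=0)
        tab = ablation_table(
            ablation_dataset, plan, targets=("fruit_fw",), seed=0,
        )
        best = tab.loc[tab["delta_r2"].idxmax(), "group"]
        assert best == "temporal"

    def test_duplicated_information_gives_near_zero_delta(self, ablation_dataset):
        """If the temporal signal is duplicated into a kept column, removing
        the temporal group costs (almost) nothing."""
        df = ablation_dataset.copy()
        df["plant_height"] = df["dat"].astype(float) + 1.0  # 'basic' mirrors DAT
        plan = make_fold_plan(df, 5, 1, seed=0)
        row = ablate_group(df, "temporal", plan, "fruit_fw", seed=0)
        assert abs(row["delta_r2"]) < 0.02

    def test_constant_group_has_no_contribution(self, ablation_dataset):
        df = ablation_dataset.copy()
        df["pruning"] = 0  # management group now all-constant (single treatment level kept)
        df["treatment"] = "CT"
        plan = make_fold_plan(df, 5, 1, seed=0)
        row = ablate_group(df, "management", plan, "fruit_fw", seed=0)
        assert abs(row["delta_r2"]) < 0.02


class TestImportanceReport:
    def test_sections_and_flags(self, ablation_dataset):
        plan = make_fold_plan(ablation_dataset, 5, 1, seed=0)
        tab = ablation_table(ablation_dataset, plan, targets=("fruit_fw",),
                             groups=("temporal",), seed=0)
        rep = importance_report(ablation=tab, attribution=None)
        assert "ablation" in rep
        assert "attribution section missing" in rep["flags"]
        assert "fruit_fw" in rep["ablation"]

    def test_every_feature_in_exactly_one_group(self):
        from pepperfw.learners import FEATURE_GROUPS

        feats = [f for g in FEATURE_GROUPS.values() for f in g]
        assert len(feats) == len(set(feats)) == 11
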