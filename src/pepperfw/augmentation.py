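"""Group-wise tabular augmentation with KL-divergence quality control.

The destructive-sampling design leaves many (season, treatment, DAT)
cells with only a handful of plants.  Augmentation therefore runs
independently within each such group, which preserves developmental
stage and treatment-specific growth patterns:

* groups with at most ``n_thr`` plants (default 10) are expanded by
  resampling rows and adding Gaussian noise at 0.05 x the within-group
  feature standard deviation;
* larger groups train a small VAE on the group's standardized
  continuous features and decode standard-normal latent draws.

Per group at most 10x the original number of samples is generated.
Categorical / discrete fields (season, treatment, DAT, pruning, year,
cultivar) are never generated: they are reassigned from the source
group after sampling.  Marginal histogram KL divergence between
original and synthetic values, averaged over the continuous features,
serves as the quality diagnostic (acceptability bound: mean KL <= 1),
and a sweep over candidate size thresholds picks the one minimizing it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import CONTINUOUS_COLUMNS, GROUP_KEYS, group_key_string, originals
from .vae import VAEConfig, decode_samples, train_vae_on_matrix

__all__ = [
    "AugmentationConfig",
    "AugmentedBatch",
    "partition_groups",
    "augment_gaussian",
    "train_vae",
    "sample_vae",
    "kl_divergence_marginal",
    "augment_dataset",
    "select_threshold",
]

MAX_FACTOR = 10  # hard cap: synthetic count <= 10x group size


@dataclass(frozen=True)
class AugmentationConfig:
    """Knobs of the group-wise augmentation protocol."""

    n_thr: int = 10  # group size at or below which the Gaussian path is used
    noise_scale: float = 0.05  # Gaussian noise sd = noise_scale * sigma_f
    factor: int = 10  # synthetic rows per original row (<= MAX_FACTOR)
    vae: VAEConfig = field(default_factory=VAEConfig)
    perturb_targets: bool = True  # Gaussian path also perturbs the FW targets
    seed: int = 0

    def validate(self) -> None:
        if self.n_thr < 1:
            raise ValueError(f"n_thr must be >= 1, got {self.n_thr}")
        if self.noise_scale <= 0:
            raise ValueError(f"noise_scale must be > 0, got {self.noise_scale}")
        if not 1 <= self.factor <= MAX_FACTOR:
            raise ValueError(
                f"factor must be in [1, {MAX_FACTOR}], got {self.factor}"
            )


@dataclass
class AugmentedBatch:
    """Synthetic rows for one source group, with provenance and diagnostics."""

    records: pd.DataFrame  # is_synthetic=True, source_group set
    generator: str  # "gaussian" | "vae"
    group_key: tuple
    kl_per_feature: dict[str, float] = field(default_factory=dict)
    loss_trace: list[float] | None = None  # VAE only


class GroupRoutingError(ValueError):
    """A group was sent down the wrong generator path for its size."""


def group_rng(seed: int, key: tuple) -> np.random.Generator:
    """Per-group RNG derived from the master seed and a stable key hash.

    Group results are therefore independent of the order in which groups
    are processed.
    """
    digest = zlib.crc32(group_key_string(*key).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def partition_groups(records: pd.DataFrame) -> dict[tuple, pd.DataFrame]:
    """Disjoint, exhaustive partition of the original records by group key."""
    orig = originals(records)
    out: dict[tuple, pd.DataFrame] = {}
    if len(orig) == 0:
        return out
    for key, sub in orig.groupby(list(GROUP_KEYS), sort=True):
        out[tuple(key)] = sub
    return out


def _finish_batch(rows: pd.DataFrame, key: tuple) -> pd.DataFrame:
    rows = rows.copy()
    rows["season"], rows["treatment"], rows["dat"] = key[0], key[1], int(key[2])
    rows["is_synthetic"] = True
    rows["source_group"] = group_key_string(*key)
    # traits / weights cannot be negative
    for col in CONTINUOUS_COLUMNS:
        rows[col] = rows[col].clip(lower=0.0)
    return rows.reset_index(drop=True)


def augment_gaussian(
    group: pd.DataFrame,
    factor: int,
    rng: np.random.Generator,
    noise_scale: float = 0.05,
    perturb_targets: bool = True,
) -> AugmentedBatch:
    """Resample-with-replacement plus additive Gaussian noise.

    Each continuous feature of a resampled row is perturbed by zero-mean
    noise with sd ``noise_scale * sigma_f``, sigma_f the feature's
    within-group standard deviation (zero-variance features stay exact).
    Categorical and discrete fields are copied from the source rows and
    the group key reassigned.
    """
    if factor > MAX_FACTOR:
        raise ValueError(f"factor {factor} exceeds the {MAX_FACTOR}x generation cap")
    n = len(group)
    key = _key_of(group)
    m = factor * n
    picks = rng.integers(0, n, size=m)
    rows = group.iloc[picks].reset_index(drop=True)
    cols = list(CONTINUOUS_COLUMNS) if perturb_targets else [
        c for c in CONTINUOUS_COLUMNS if c not in ("shoot_fw", "fruit_fw")
    ]
    sigma = group[cols].std(ddof=1).fillna(0.0).to_numpy()
    sigma[~np.isfinite(sigma)] = 0.0
    noise = rng.standard_normal((m, len(cols))) * (noise_scale * sigma)
    rows.loc[:, cols] = rows[cols].to_numpy(dtype=float) + noise
    return AugmentedBatch(records=_finish_batch(rows, key), generator="gaussian", group_key=key)


def _key_of(group: pd.DataFrame) -> tuple:
    keys = group[list(GROUP_KEYS)].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("group must contain a single (season, treatment, dat) key")
    season, treatment, dat = keys.iloc[0]
    return (season, treatment, int(dat))


@dataclass
class GroupVAE:
    """A VAE trained on one group's standardized continuous features."""

    trained: object
    mean: np.ndarray
    sd: np.ndarray
    group: pd.DataFrame
    key: tuple
    columns: list[str]
    observation_noise: bool = False


def train_vae(
    group: pd.DataFrame, config: VAEConfig, rng: np.random.Generator, n_thr: int = 10
) -> GroupVAE:
    """Train the generative model for one large group (size > n_thr).

    Continuous features are z-scored within the group before training
    (constant features use sd 1, so they standardize to 0 and decode back
    to their constant value).
    """
    n = len(group)
    if n <= n_thr:
        raise GroupRoutingError(
            f"group of size {n} is at or below n_thr={n_thr}; use the Gaussian path"
        )
    cols = list(CONTINUOUS_COLUMNS)
    X = group[cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    trained = train_vae_on_matrix((X - mean) / sd, config, rng)
    return GroupVAE(
        trained=trained, mean=mean, sd=sd, group=group, key=_key_of(group),
        columns=cols, observation_noise=config.sample_observation_noise,
    )


def sample_vae(gen: GroupVAE, m: int, rng: np.random.Generator) -> AugmentedBatch:
    """Decode m latent draws into synthetic plant records."""
    n = len(gen.group)
    if m > MAX_FACTOR * n:
        raise ValueError(
            f"requested {m} samples exceeds the {MAX_FACTOR}x cap for a group of {n}"
        )
    Z = decode_samples(
        gen.trained, m, rng,
        observation_noise=getattr(gen, "observation_noise", False),
    )
    X = Z * gen.sd + gen.mean
    # categorical / discrete fields reassigned by sampling source rows
    picks = rng.integers(0, n, size=m) if m else np.array([], dtype=int)
    rows = gen.group.iloc[picks].reset_index(drop=True)
    rows.loc[:, gen.columns] = X
    batch = _finish_batch(rows, gen.key)
    return AugmentedBatch(
        records=batch,
        generator="vae",
        group_key=gen.key,
        loss_trace=list(gen.trained.loss_trace),
    )


def kl_divergence_marginal(
    original: np.ndarray,
    augmented: np.ndarray,
    bins: int = 20,
    eps: float = 1e-8,
) -> float:
    """Histogram estimate of KL(original || augmented) for one feature.

    Shared equal-width bin edges over the pooled min-max range, additive
    smoothing ``eps`` on both histograms before normalization, natural
    log.  Identical samples give 0 (within smoothing tolerance); the
    estimate is always >= 0 up to smoothing.
    """
    original = np.asarray(original, dtype=float)
    augmented = np.asarray(augmented, dtype=float)
    if len(original) == 0 or len(augmented) == 0:
        raise ValueError("kl_divergence_marginal requires non-empty inputs")
    lo = min(original.min(), augmented.min())
    hi = max(original.max(), augmented.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(original, bins=edges)
    q, _ = np.histogram(augmented, bins=edges)
    p = p.astype(float) + eps
    q = q.astype(float) + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def mean_marginal_kl(
    original: pd.DataFrame, synthetic: pd.DataFrame, bins: int = 20
) -> tuple[float, dict[str, float]]:
    """Feature-averaged marginal KL between pooled original and synthetic rows."""
    per_feature = {
        col: kl_divergence_marginal(
            original[col].to_numpy(dtype=float),
            synthetic[col].to_numpy(dtype=float),
            bins=bins,
        )
        for col in CONTINUOUS_COLUMNS
    }
    return float(np.mean(list(per_feature.values()))), per_feature


def augment_dataset(
    records: pd.DataFrame, config: AugmentationConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Augment every group of the original records; originals untouched.

    Routing: groups with size <= ``n_thr`` use the Gaussian-noise path,
    larger groups the VAE path; both generate ``factor`` x group-size
    synthetic rows.  Returns (originals + synthetic rows, report) where
    the report carries per-group generator, counts and per-feature KL,
    plus the overall feature-averaged KL.
    """
    config = config or AugmentationConfig()
    config.validate()
    orig = originals(records).reset_index(drop=True)
    groups = partition_groups(orig)
    batches: list[AugmentedBatch] = []
    report: dict = {"groups": {}, "config": {"n_thr": config.n_thr, "factor": config.factor}}
    for key in sorted(groups):
        sub = groups[key]
        rng = group_rng(config.seed, key)
        try:
            if len(sub) <= config.n_thr:
                batch = augment_gaussian(
                    sub, config.factor, rng,
                    noise_scale=config.noise_scale,
                    perturb_targets=config.perturb_targets,
                )
            else:
                gen = train_vae(sub, config.vae, rng, n_thr=config.n_thr)
                batch = sample_vae(gen, config.factor * len(sub), rng)
        except Exception as exc:  # noqa: BLE001 - annotate failing group
            raise RuntimeError(
                f"augmentation failed for group {group_key_string(*key)}: {exc}"
            ) from exc
        _, per_feature = mean_marginal_kl(sub, batch.records)
        batch.kl_per_feature = per_feature
        report["groups"][group_key_string(*key)] = {
            "generator": batch.generator,
            "n_original": int(len(sub)),
            "n_synthetic": int(len(batch.records)),
            "kl_per_feature": per_feature,
            "kl_mean": float(np.mean(list(per_feature.values()))),
        }
        batches.append(batch)
    synth = (
        pd.concat([b.records for b in batches], ignore_index=True)
        if batches
        else orig.iloc[0:0]
    )
    overall_kl, overall_per_feature = (
        mean_marginal_kl(orig, synth) if len(synth) else (float("nan"), {})
    )
    report["overall"] = {
        "kl_mean": overall_kl,
        "kl_per_feature": overall_per_feature,
        "n_original": int(len(orig)),
        "n_synthetic": int(len(synth)),
    }
    combined = pd.concat([orig, synth], ignore_index=True)
    return combined, report


def select_threshold(
    records: pd.DataFrame,
    candidates: tuple[int, ...] = (3, 5, 7, 10),
    config: AugmentationConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Sweep size thresholds and pick the one minimizing mean marginal KL.

    Runs the full augmentation once per candidate ``n_thr`` and compares
    the feature-averaged KL between the pooled original and synthetic
    rows.  Ties break toward the larger threshold.  If no group exceeds
    the largest candidate the sweep degenerates (all candidates give the
    Gaussian-only augmentation) and a warning is attached to the table.
    """
    if len(candidates) == 0:
        raise ValueError("candidates must be non-empty")
    base = config or AugmentationConfig()
    groups = partition_groups(records)
    sizes = [len(g) for g in groups.values()]
    degenerate = not any(s > max(candidates) for s in sizes)
    rows = []
    for cand in sorted(candidates):
        cfg = AugmentationConfig(
            n_thr=cand,
            noise_scale=base.noise_scale,
            factor=base.factor,
            vae=base.vae,
            perturb_targets=base.perturb_targets,
            seed=base.seed,
        )
        _, report = augment_dataset(records, cfg)
        rows.append(
            {
                "n_thr": cand,
                "kl_mean": report["overall"]["kl_mean"],
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows).sort_values("n_thr").reset_index(drop=True)
    best = table["kl_mean"].min()
    # ties toward the larger threshold
    chosen = int(table.loc[np.isclose(table["kl_mean"], best), "n_thr"].max())
    return chosen, table
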