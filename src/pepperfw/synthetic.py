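"""Synthetic plant-record generator.

The greenhouse measurement campaign behind this pipeline — five growing
seasons of destructively sampled two-stem sweet pepper under three
interlighting treatments — was never deposited as a raw table, so the
package carries a generator that emulates its sampling design (the
year / season / cultivar / treatment / days-after-transplanting cells
and their sample counts) and the statistical relationships the analysis
assumes:

* each morphological trait follows a logistic growth curve in DAT with
  multiplicative lognormal noise (growth saturates late in the season);
* shoot fresh weight is a logistic (sigmoid) function of "stick volume",
  the summed length of the three stem segments — an allometric link;
* cumulative fruit fresh weight is driven primarily by DAT (a cumulative
  logistic starting after a fruiting-onset day), with only a small
  structural modulation and small management effects.

Trait logistic midpoints sit well before the fruit midpoint, so late in
the season the traits saturate while fruit mass is still accumulating:
developmental time then carries information about fruit FW that the
structure no longer does, which is the organ-specific pattern the
downstream interpretation stages are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import COLUMNS, TRAIT_COLUMNS, validate_records

__all__ = [
    "DesignRow",
    "TraitCurve",
    "SimConfig",
    "study_design",
    "generate_dataset",
]


@dataclass(frozen=True)
class DesignRow:
    """One sampling cell: how many plants were destructively measured."""

    year: int
    season: str
    cultivar: str
    treatment: str
    dat: int
    n: int


def study_design() -> list[DesignRow]:
    """The five-season greenhouse sampling design (303 plants, 36 cells)."""
    raw = [
        # year, season, cultivar, treatment, dat, n
        (2020, "spring", "Scirocco", "CT", 30, 3),
        (2020, "spring", "Scirocco", "CT", 56, 3),
        (2020, "spring", "Scirocco", "CT", 84, 3),
        (2020, "spring", "Scirocco", "CT", 113, 4),
        (2020, "spring", "Scirocco", "CT", 133, 20),
        (2020, "spring", "Scirocco", "RB", 84, 3),
        (2020, "spring", "Scirocco", "RB", 133, 12),
        (2020, "spring", "Scirocco", "FR", 84, 3),
        (2020, "spring", "Scirocco", "FR", 133, 12),
        (2020, "winter", "Mavera/Florate", "CT", 50, 6),
        (2020, "winter", "Mavera/Florate", "CT", 80, 6),
        (2020, "winter", "Mavera/Florate", "CT", 108, 3),
        (2020, "winter", "Mavera/Florate", "CT", 153, 15),
        (2020, "winter", "Mavera/Florate", "RB", 108, 3),
        (2020, "winter", "Mavera/Florate", "RB", 153, 13),
        (2020, "winter", "Mavera/Florate", "FR", 108, 3),
        (2020, "winter", "Mavera/Florate", "FR", 153, 12),
        (2021, "spring", "Mavera/Florate", "CT", 40, 5),
        (2021, "spring", "Mavera/Florate", "CT", 60, 5),
        (2021, "spring", "Mavera/Florate", "CT", 80, 5),
        (2021, "spring", "Mavera/Florate", "CT", 100, 5),
        (2021, "spring", "Mavera/Florate", "CT", 120, 10),
        (2021, "spring", "Mavera/Florate", "RB", 40, 5),
        (2021, "spring", "Mavera/Florate", "RB", 60, 5),
        (2021, "spring", "Mavera/Florate", "RB", 80, 5),
        (2021, "spring", "Mavera/Florate", "RB", 100, 5),
        (2021, "spring", "Mavera/Florate", "RB", 120, 10),
        (2021, "spring", "Mavera/Florate", "FR", 40, 9),
        (2021, "spring", "Mavera/Florate", "FR", 60, 10),
        (2021, "spring", "Mavera/Florate", "FR", 80, 10),
        (2021, "spring", "Mavera/Florate", "FR", 100, 10),
        (2021, "spring", "Mavera/Florate", "FR", 120, 20),
        (2021, "winter", "Mavera", "CT", 150, 9),
        (2021, "winter", "Mavera", "RB", 150, 9),
        (2021, "winter", "Mavera", "FR", 150, 36),
        (2022, "spring", "Mavera", "CT", 61, 6),
    ]
    return [DesignRow(*row) for row in raw]


@dataclass(frozen=True)
class TraitCurve:
    """Logistic growth curve for one trait: asymptote / rate / midpoint.

    ``value(dat) = asymptote / (1 + exp(-rate * (dat - midpoint)))``
    """

    asymptote: float
    rate: float
    midpoint: float

    def value(self, dat) -> np.ndarray:
        dat = np.asarray(dat, dtype=float)
        return self.asymptote / (1.0 + np.exp(-self.rate * (dat - self.midpoint)))


# Default trait curves.  Midpoints near DAT 70 with rate ~0.028 put the
# traits at ~90% of their asymptote by DAT 150 (saturating growth).
_DEFAULT_TRAITS: dict[str, TraitCurve] = {
    "basal_stem_diam": TraitCurve(asymptote=15.0, rate=0.030, midpoint=60.0),
    "main_stem_diam": TraitCurve(asymptote=12.0, rate=0.028, midpoint=65.0),
    "left_stem_diam": TraitCurve(asymptote=10.0, rate=0.028, midpoint=70.0),
    "right_stem_diam": TraitCurve(asymptote=10.0, rate=0.028, midpoint=70.0),
    "main_stem_len": TraitCurve(asymptote=45.0, rate=0.035, midpoint=50.0),
    "left_stem_len": TraitCurve(asymptote=180.0, rate=0.028, midpoint=72.0),
    "right_stem_len": TraitCurve(asymptote=180.0, rate=0.028, midpoint=72.0),
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Attributes
    ----------
    design:
        Sampling cells; defaults to the five-season greenhouse design.
    traits:
        Per-trait logistic growth curves (diameters in mm, lengths in cm).
        ``plant_height`` is derived rather than independently drawn: main
        segment + the longer lateral segment + ``canopy_offset``, with its
        own multiplicative measurement noise at ``cv_trait``.
    shoot_L, shoot_k, shoot_V0:
        Allometric sigmoid linking shoot FW (g) to stick volume (cm):
        ``shoot = L / (1 + exp(-k (V - V0)))``.
    fruit_max, fruit_rate, fruit_midpoint, fruit_onset_dat:
        Cumulative-fruit logistic in DAT; identically 0 before the onset.
    structural_weight:
        Relative modulation of fruit FW by standardized stick volume
        (small: structure is secondary for fruit mass).
    treatment_fruit_effect:
        Multiplier per lighting treatment on fruit FW (within +/-5%).
    pruning_shoot_effect:
        Multiplier on shoot FW for pruned plants (within +/-3%).
    pruning_prob:
        Probability that a plant's main stem was pruned.
    cv_trait, cv_target:
        Coefficients of variation of the multiplicative lognormal noise.
    canopy_offset:
        Height (cm) added above the top stem segment.
    """

    design: tuple[DesignRow, ...] = field(
        default_factory=lambda: tuple(study_design())
    )
    traits: dict[str, TraitCurve] = field(default_factory=lambda: dict(_DEFAULT_TRAITS))
    shoot_L: float = 4000.0
    shoot_k: float = 0.010
    shoot_V0: float = 450.0
    fruit_max: float = 3000.0
    fruit_rate: float = 0.06
    fruit_midpoint: float = 115.0
    fruit_onset_dat: float = 45.0
    structural_weight: float = 0.10
    treatment_fruit_effect: dict[str, float] = field(
        default_factory=lambda: {"CT": 1.0, "RB": 1.03, "FR": 1.05}
    )
    pruning_shoot_effect: float = 0.97
    pruning_prob: float = 0.3
    cv_trait: float = 0.08
    cv_target: float = 0.12
    canopy_offset: float = 10.0
    seed: int = 42

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def validate(self) -> None:
        for i, row in enumerate(self.design):
            if row.n < 1:
                raise ValueError(f"design row {i}: n must be >= 1, got {row.n}")
        for name in ("cv_trait", "cv_target"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        missing = [t for t in TRAIT_COLUMNS if t != "plant_height" and t not in self.traits]
        if missing:
            raise ValueError(f"traits: missing curve(s) for {missing}")
        for name in ("shoot_L", "shoot_k", "fruit_max", "fruit_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not np.isfinite(self.structural_weight):
            raise ValueError("structural_weight must be finite")
        for trt, eff in self.treatment_fruit_effect.items():
            if not np.isfinite(eff):
                raise ValueError(f"treatment_fruit_effect[{trt!r}] must be finite")
        if not 0.0 <= self.pruning_prob <= 1.0:
            raise ValueError(f"pruning_prob must be in [0, 1], got {self.pruning_prob}")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def generate_dataset(config: SimConfig | None = None) -> pd.DataFrame:
    """Generate one record per design-cell slot; deterministic given the seed.

    Traits are drawn per cell from their logistic curves, shoot FW from the
    allometric sigmoid of stick volume, fruit FW from the DAT-driven
    cumulative logistic with small structural/management modulation.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    frames = []
    for row in config.design:
        n = row.n
        rec: dict[str, np.ndarray] = {}
        for name, curve in config.traits.items():
            rec[name] = curve.value(row.dat) * _lognormal_factor(rng, config.cv_trait, n)
        # height is its own ruler measurement: derived from the segments but
        # carrying the same multiplicative measurement noise as any trait
        rec["plant_height"] = (
            rec["main_stem_len"]
            + np.maximum(rec["left_stem_len"], rec["right_stem_len"])
            + config.canopy_offset
        ) * _lognormal_factor(rng, config.cv_trait, n)
        pruning = (rng.random(n) < config.pruning_prob).astype(int)

        stick = rec["main_stem_len"] + rec["left_stem_len"] + rec["right_stem_len"]
        shoot = config.shoot_L / (1.0 + np.exp(-config.shoot_k * (stick - config.shoot_V0)))
        shoot = shoot * np.where(pruning == 1, config.pruning_shoot_effect, 1.0)
        shoot = shoot * _lognormal_factor(rng, config.cv_target, n)

        if row.dat < config.fruit_onset_dat:
            fruit = np.zeros(n)
        else:
            base = config.fruit_max / (
                1.0 + np.exp(-config.fruit_rate * (row.dat - config.fruit_midpoint))
            )
            # small structural modulation: standardized stick volume at this DAT
            expected_stick = sum(
                config.traits[t].value(row.dat)
                for t in ("main_stem_len", "left_stem_len", "right_stem_len")
            )
            z = (stick - expected_stick) / max(expected_stick, 1e-9)
            mod = 1.0 + config.structural_weight * z
            trt = config.treatment_fruit_effect.get(row.treatment, 1.0)
            fruit = base * np.clip(mod, 0.0, None) * trt
            fruit = fruit * _lognormal_factor(rng, config.cv_target, n)

        frames.append(
            pd.DataFrame(
                {
                    "year": row.year,
                    "season": row.season,
                    "cultivar": row.cultivar,
                    "treatment": row.treatment,
                    "dat": row.dat,
                    "pruning": pruning,
                    **{c: rec[c] for c in TRAIT_COLUMNS},
                    "shoot_fw": shoot,
                    "fruit_fw": fruit,
                    "is_synthetic": False,
                    "source_group": "",
                }
            )
        )
    df = pd.concat(frames, ignore_index=True).loc[:, list(COLUMNS)]
    return validate_records(df)
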