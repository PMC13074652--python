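"""Plant-record table schema, validation and CSV round-trip.

A *record* is one destructively sampled sweet-pepper plant: grouping keys
(year, season, cultivar, lighting treatment, days after transplanting),
morphological traits, management flags, the two regression targets
(shoot fresh weight and cumulative harvested fruit fresh weight), and
augmentation provenance (``is_synthetic``, ``source_group``).

Units: cm for plant height and stem segment lengths, mm for stem
diameters, g for fresh weights.
"""

from __future__ import annotations

import pandas as pd

#: Allowed categorical levels.
SEASONS = ("spring", "winter")
TREATMENTS = ("CT", "RB", "FR")

#: Morphological trait columns (continuous, strictly positive except
#: segment lengths which may be 0 very early in development).
TRAIT_COLUMNS = (
    "plant_height",
    "basal_stem_diam",
    "main_stem_diam",
    "left_stem_diam",
    "right_stem_diam",
    "main_stem_len",
    "left_stem_len",
    "right_stem_len",
)

#: Regression targets (g).
TARGET_COLUMNS = ("shoot_fw", "fruit_fw")

#: Continuous columns handled by the generative augmentation paths.
CONTINUOUS_COLUMNS = TRAIT_COLUMNS + TARGET_COLUMNS

#: Grouping keys used for group-wise augmentation.
GROUP_KEYS = ("season", "treatment", "dat")

#: Full CSV header, in order.
COLUMNS = (
    "year",
    "season",
    "cultivar",
    "treatment",
    "dat",
    "pruning",
    *TRAIT_COLUMNS,
    *TARGET_COLUMNS,
    "is_synthetic",
    "source_group",
)


class RecordValidationError(ValueError):
    """Raised when a record table violates the schema."""


def group_key_string(season: str, treatment: str, dat: int) -> str:
    """Serialize a (season, treatment, dat) group key, e.g. ``spring|CT|133``."""
    return f"{season}|{treatment}|{int(dat)}"


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a record table against the schema.

    Returns the (unmodified) frame if valid; raises
    :class:`RecordValidationError` naming the offending column otherwise.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"missing required column(s): {missing}")
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise RecordValidationError(f"unknown column(s): {unknown}")

    bad_season = set(df["season"]) - set(SEASONS)
    if bad_season:
        raise RecordValidationError(
            f"unknown season value(s) {sorted(bad_season)}; allowed: {list(SEASONS)}"
        )
    bad_trt = set(df["treatment"]) - set(TREATMENTS)
    if bad_trt:
        raise RecordValidationError(
            f"unknown treatment value(s) {sorted(bad_trt)}; allowed: {list(TREATMENTS)}"
        )

    for col in ("dat", "year", "pruning", *CONTINUOUS_COLUMNS):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise RecordValidationError(f"non-numeric or missing value in column {col!r}")
    if (df["dat"].astype(float) < 0).any():
        raise RecordValidationError("dat must be >= 0")
    for col in CONTINUOUS_COLUMNS:
        if (df[col].astype(float) < 0).any():
            raise RecordValidationError(f"{col!r} must be >= 0")
    strictly_pos = (
        "plant_height",
        "basal_stem_diam",
        "main_stem_diam",
        "left_stem_diam",
        "right_stem_diam",
    )
    for col in strictly_pos:
        if (df[col].astype(float) <= 0).any():
            raise RecordValidationError(f"{col!r} must be strictly positive")
    return df


def write_records(df: pd.DataFrame, path) -> None:
    """Write a record table to CSV (UTF-8, documented header order)."""
    validate_records(df)
    out = df.loc[:, list(COLUMNS)].copy()
    out["source_group"] = out["source_group"].fillna("")
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read and validate a record-table CSV written by :func:`write_records`."""
    df = pd.read_csv(
        path,
        dtype={"season": str, "cultivar": str, "treatment": str, "source_group": str},
        keep_default_na=False,
        na_values=[],
    )
    for col in ("year", "dat"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in CONTINUOUS_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "pruning" in df.columns:
        df["pruning"] = pd.to_numeric(df["pruning"], errors="coerce")
    if "is_synthetic" in df.columns:
        df["is_synthetic"] = df["is_synthetic"].astype(str).str.lower().isin(("true", "1"))
    validate_records(df)
    df["year"] = df["year"].astype(int)
    df["dat"] = df["dat"].astype(int)
    df["pruning"] = df["pruning"].astype(int)
    return df


def originals(df: pd.DataFrame) -> pd.DataFrame:
    """Subset of measured (non-synthetic) records."""
    return df.loc[~df["is_synthetic"].astype(bool)]
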