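"""Geometric volume proxies and allometric scaling fits.

Two-stem sweet pepper is approximated by three longitudinal segments
(main/trunk, left, right).  Three geometric proxies of increasing detail
turn the measured segment lengths and diameters into a whole-plant
"volume" V, and fresh weight is then modeled as either a proportional
(linear) or saturating (logistic sigmoid) function of V:

* ``stick``          — V = sum of segment lengths (cm); a pure length
                       proxy.  ``stick_mode="height"`` uses plant height
                       instead.
* ``cylinder``       — each segment is a cylinder with its own diameter;
                       V in cm^3.
* ``truncated_cone`` — each segment tapers proximal-to-distal between
                       two radii; V in cm^3.

linear:  FW = alpha * V + beta
sigmoid: FW = L / (1 + exp(-k (V - V0)))   (L: asymptotic FW in g,
         k: rate per volume unit, V0: inflection volume; FW(V0) = L/2)

The sigmoid is fitted by nonlinear least squares; when it fails to
converge or returns a degenerate asymptote, the fit falls back to the
linear form (``fallback_used`` is set) so a baseline always exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .evaluation import r2 as _r2, rmse as _rmse

GEOMETRIES = ("stick", "cylinder", "truncated_cone")
FORMS = ("linear", "sigmoid")

_SEGMENTS = ("main", "left", "right")


class DegenerateDesignError(ValueError):
    """All volumes identical: no scaling relationship can be estimated."""


class InsufficientDataError(ValueError):
    """Too few points for the requested functional form."""


def _segment_lengths(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {s: df[f"{s}_stem_len"].to_numpy(dtype=float) for s in _SEGMENTS}


def _radii_cm(df: pd.DataFrame, col: str) -> np.ndarray:
    """Radius in cm from a diameter column in mm."""
    return df[col].to_numpy(dtype=float) / 10.0 / 2.0


def volume(records: pd.DataFrame, geometry: str, stick_mode: str = "segments") -> np.ndarray:
    """Whole-plant volume proxy per record.

    stick: cm (a length); cylinder / truncated_cone: cm^3.  Diameters are
    measured in mm and converted to cm before use.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; allowed: {list(GEOMETRIES)}")
    L = _segment_lengths(records)
    for s, lv in L.items():
        if (lv < 0).any():
            raise ValueError(f"negative {s} stem length")

    if geometry == "stick":
        if stick_mode == "height":
            return records["plant_height"].to_numpy(dtype=float)
        if stick_mode != "segments":
            raise ValueError(f"unknown stick_mode {stick_mode!r}")
        return L["main"] + L["left"] + L["right"]

    diam_cols = (
        "basal_stem_diam",
        "main_stem_diam",
        "left_stem_diam",
        "right_stem_diam",
    )
    for col in diam_cols:
        if (records[col].to_numpy(dtype=float) <= 0).any():
            raise ValueError(f"non-positive diameter in {col!r}")

    if geometry == "cylinder":
        # each segment a cylinder with its own measured diameter
        v = np.zeros(len(records))
        for s in _SEGMENTS:
            r = _radii_cm(records, f"{s}_stem_diam")
            v += np.pi * r**2 * L[s]
        return v

    # truncated cone: proximal-to-distal taper.  Main segment tapers from
    # the basal to the main diameter; laterals from the main diameter to
    # their own.
    r_basal = _radii_cm(records, "basal_stem_diam")
    r_main = _radii_cm(records, "main_stem_diam")
    v = _frustum(L["main"], r_basal, r_main)
    for s in ("left", "right"):
        v += _frustum(L[s], r_main, _radii_cm(records, f"{s}_stem_diam"))
    return v


def _frustum(length: np.ndarray, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Volume of a conical frustum: pi*L/3 * (r1^2 + r1 r2 + r2^2)."""
    return np.pi * length / 3.0 * (r1**2 + r1 * r2 + r2**2)


@dataclass
class AllometricFit:
    """A fitted scaling law and its diagnostics."""

    geometry: str
    form: str  # "linear" | "sigmoid"
    params: dict[str, float]
    sse: float
    converged: bool
    fallback_used: bool = False
    stick_mode: str = "segments"

    def predict_volume(self, V) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        p = self.params
        if self.form == "linear":
            return p["alpha"] * V + p["beta"]
        return p["L"] / (1.0 + np.exp(-p["k"] * (V - p["V0"])))

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        return self.predict_volume(volume(records, self.geometry, self.stick_mode))


def fit_linear(V, FW, geometry: str = "stick") -> AllometricFit:
    """Ordinary least squares FW = alpha*V + beta."""
    V = np.asarray(V, dtype=float)
    FW = np.asarray(FW, dtype=float)
    if len(np.unique(V)) < 2:
        raise DegenerateDesignError("all volumes identical; linear fit undefined")
    A = np.column_stack([V, np.ones_like(V)])
    coef, *_ = np.linalg.lstsq(A, FW, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    sse = float(np.sum((A @ coef - FW) ** 2))
    return AllometricFit(
        geometry=geometry,
        form="linear",
        params={"alpha": alpha, "beta": beta},
        sse=sse,
        converged=True,
    )


def _sigmoid(V, L, k, V0):
    return L / (1.0 + np.exp(-k * (V - V0)))


def fit_sigmoid(V, FW, geometry: str = "stick", maxfev: int = 10_000) -> AllometricFit:
    """Nonlinear least squares for the logistic form, with linear fallback.

    Initialization: L0 = 1.1*max(FW), V0 = median(V), k0 = 4/range(V).
    On optimizer failure or a non-finite / non-positive asymptote the
    linear form is refitted and ``fallback_used`` set.  Fewer than 4
    points raises (3 parameters; no silent fallback).
    """
    V = np.asarray(V, dtype=float)
    FW = np.asarray(FW, dtype=float)
    if len(V) < 4:
        raise InsufficientDataError(f"sigmoid fit needs >= 4 points, got {len(V)}")
    vrange = float(np.ptp(V))
    fwmax = float(np.max(FW))
    if vrange == 0:
        return _fallback(V, FW, geometry)
    p0 = [1.1 * fwmax if fwmax > 0 else 1.0, 4.0 / vrange, float(np.median(V))]
    bounds = (
        [1e-12, 1e-12, float(np.min(V))],
        [10.0 * max(fwmax, 1.0), np.inf, float(np.max(V))],
    )
    try:
        popt, _ = curve_fit(
            _sigmoid, V, FW, p0=p0, bounds=bounds, maxfev=maxfev, ftol=1e-10, xtol=1e-12
        )
    except (RuntimeError, ValueError):
        return _fallback(V, FW, geometry)
    L, k, V0 = (float(x) for x in popt)
    if not np.isfinite([L, k, V0]).all() or L <= 0:
        return _fallback(V, FW, geometry)
    # a rate pinned at its lower bound is a flat curve, not a convergence:
    # the optimizer stalled on data with no rising sigmoid shape
    if k <= 1e-9 or L >= bounds[1][0] * (1 - 1e-9):
        return _fallback(V, FW, geometry)
    resid = _sigmoid(V, L, k, V0) - FW
    return AllometricFit(
        geometry=geometry,
        form="sigmoid",
        params={"L": L, "k": k, "V0": V0},
        sse=float(np.sum(resid**2)),
        converged=True,
    )


def _fallback(V, FW, geometry: str) -> AllometricFit:
    fit = fit_linear(V, FW, geometry)
    fit.fallback_used = True
    fit.converged = False
    return fit


def fit(V, FW, form: str, geometry: str = "stick") -> AllometricFit:
    if form == "linear":
        return fit_linear(V, FW, geometry)
    if form == "sigmoid":
        return fit_sigmoid(V, FW, geometry)
    raise ValueError(f"unknown form {form!r}; allowed: {list(FORMS)}")


def evaluate_allometric(
    records: pd.DataFrame,
    plan,
    targets=("shoot_fw", "fruit_fw"),
    geometries=GEOMETRIES,
    forms=FORMS,
    stick_mode: str = "segments",
) -> pd.DataFrame:
    """Cross-validated R^2/RMSE for every geometry x form x target.

    Fits are made on each training fold of the shared fold plan and
    scored on the out-of-fold records; per-fit failures are recorded in
    the ``n_fallback`` column, not raised.  Returns a tidy frame with
    mean +/- sd over repeats.
    """
    from .records import originals

    orig = originals(records).reset_index(drop=True)
    rows = []
    for geometry in geometries:
        V_all = volume(orig, geometry, stick_mode)
        for form in forms:
            for target in targets:
                y = orig[target].to_numpy(dtype=float)
                per_repeat_r2, per_repeat_rmse = [], []
                n_fallback = 0
                for rep in range(plan.repeats):
                    oof = np.full(len(orig), np.nan)
                    for k in range(plan.k):
                        train_idx, test_idx = plan.split(rep, k)
                        f = fit(V_all[train_idx], y[train_idx], form, geometry)
                        n_fallback += int(f.fallback_used)
                        oof[test_idx] = f.predict_volume(V_all[test_idx])
                    per_repeat_r2.append(_r2(y, oof))
                    per_repeat_rmse.append(_rmse(y, oof))
                rows.append(
                    {
                        "geometry": geometry,
                        "form": form,
                        "target": target,
                        "r2_mean": float(np.mean(per_repeat_r2)),
                        "r2_sd": float(np.std(per_repeat_r2, ddof=1))
                        if plan.repeats > 1
                        else 0.0,
                        "rmse_mean": float(np.mean(per_repeat_rmse)),
                        "rmse_sd": float(np.std(per_repeat_rmse, ddof=1))
                        if plan.repeats > 1
                        else 0.0,
                        "n_fallback": n_fallback,
                    }
                )
    return pd.DataFrame(rows)
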