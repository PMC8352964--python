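"""Differential small-molecule sensitivity: viability normalization,
logistic dose-response fitting, AUC, and median-centered delta-AUC ranking.

The dose-response model is the standard inhibitor-response logistic on the
log10-dose axis,

    v(d) = bottom + (top - bottom) / (1 + 10^((log10 d - log10 EC50) * hill)),

fit in three-parameter mode (hill fixed at 1) by default.  AUC is the
integral of viability over log10 dose across the tested range divided by the
range width, so a constant viability v yields AUC = v and values from
different compounds/dose ranges are comparable on a [0, ~top] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

LN10 = np.log(10.0)


def logistic(dose: np.ndarray, top: float, bottom: float,
             log10_ec50: float, hill: float = 1.0) -> np.ndarray:
    """Inhibitor-response logistic evaluated at (linear-scale) doses."""
    dose = np.asarray(dose, dtype=float)
    x = np.log10(dose)
    u = hill * LN10 * (x - log10_ec50)
    return bottom + (top - bottom) / (1.0 + np.exp(u))


@dataclass
class DoseResponse:
    """Fitted dose-response for one compound in one cell line."""

    compound: str
    doses: np.ndarray
    viability: np.ndarray  # mean viability per dose
    top: float
    bottom: float
    log10_ec50: float
    hill: float
    converged: bool
    auc: float


def normalize_viability(luminescence, reference_luminescence) -> np.ndarray:
    """Viability fraction: test luminescence over the mean reference signal."""
    ref = np.asarray(reference_luminescence, dtype=float)
    if (ref <= 0).any():
        raise ValueError("reference luminescence must be positive")
    return np.asarray(luminescence, dtype=float) / ref.mean()


def _model3(log10_dose, top, frac, log10_ec50):
    # bottom parameterized as top*frac so the bound bottom <= top is built in
    bottom = top * frac
    u = LN10 * (log10_dose - log10_ec50)
    return bottom + (top - bottom) / (1.0 + np.exp(u))


def _model4(log10_dose, top, frac, log10_ec50, hill):
    bottom = top * frac
    u = hill * LN10 * (log10_dose - log10_ec50)
    return bottom + (top - bottom) / (1.0 + np.exp(u))


def fit_dose_response(
    doses,
    viability,
    compound: str = "",
    fix_hill: bool = True,
) -> DoseResponse:
    """Least-squares logistic fit of mean viability against log10 dose.

    Three-parameter mode (default) fixes hill = 1.  Bounds: top in [0, 1.5],
    bottom in [0, top], log10 EC50 within two decades of the tested range.
    On non-convergence the result is flagged and the AUC falls back to the
    trapezoid rule on the raw points.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.size < 4:
        raise ValueError("need at least 4 dose points to fit")
    if not np.all(np.diff(doses) > 0):
        order = np.argsort(doses)
        doses, viability = doses[order], viability[order]
    x = np.log10(doses)
    lo, hi = x.min() - 2.0, x.max() + 2.0
    v0 = float(np.clip(viability.max(), 1e-6, 1.5))
    frac0 = float(np.clip(viability.min() / v0, 0.0, 1.0))
    p0 = [v0, frac0, float(x.mean())]
    bounds_lo, bounds_hi = [0.0, 0.0, lo], [1.5, 1.0, hi]
    converged = True
    tol = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=50000)
    try:
        if fix_hill:
            popt, _ = curve_fit(_model3, x, viability, p0=p0,
                                bounds=(bounds_lo, bounds_hi), **tol)
            top, frac, c = popt
            hill = 1.0
        else:
            popt, _ = curve_fit(_model4, x, viability, p0=p0 + [1.0],
                                bounds=(bounds_lo + [0.1], bounds_hi + [10.0]),
                                **tol)
            top, frac, c, hill = popt
        bottom = top * frac
    except RuntimeError:
        converged = False
        top, bottom, c, hill = np.nan, np.nan, np.nan, np.nan
    if converged:
        a = auc_logistic(top, bottom, c, hill, x.min(), x.max())
    else:
        a = float(np.trapezoid(viability, x) / (x.max() - x.min()))
    return DoseResponse(compound, doses, viability, float(top), float(bottom),
                        float(c), float(hill), converged, a)


def auc_logistic(top: float, bottom: float, log10_ec50: float, hill: float,
                 x0: float, x1: float) -> float:
    """Closed-form mean of the logistic over [x0, x1] on the log10-dose axis.

    Uses int 1/(1+e^u) dx = x - log(1+e^u)/(hill*ln10), evaluated stably via
    logaddexp.
    """
    if x1 <= x0:
        raise ValueError("need x1 > x0 (a single dose has no AUC)")
    k = hill * LN10
    u0, u1 = k * (x0 - log10_ec50), k * (x1 - log10_ec50)
    if k == 0.0:
        mean_sigmoid = 0.5
    else:
        integral = (x1 - x0) - (np.logaddexp(0.0, u1) - np.logaddexp(0.0, u0)) / k
        mean_sigmoid = integral / (x1 - x0)
    return float(bottom + (top - bottom) * mean_sigmoid)


def auc(curve: DoseResponse | None = None, *, doses=None, viability=None) -> float:
    """AUC over the tested log10-dose range, normalized by the range width.

    With a fitted ``DoseResponse`` the closed-form integral of the fitted
    curve is used; with raw points the trapezoid rule is used.
    """
    if curve is not None:
        if not curve.converged:
            x = np.log10(curve.doses)
            return float(np.trapezoid(curve.viability, x) / (x.max() - x.min()))
        x = np.log10(curve.doses)
        return auc_logistic(curve.top, curve.bottom, curve.log10_ec50,
                            curve.hill, x.min(), x.max())
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.size < 2:
        raise ValueError("need at least 2 doses to integrate")
    x = np.log10(doses)
    return float(np.trapezoid(viability, x) / (x.max() - x.min()))


def fit_plate(
    plate: pd.DataFrame,
    fix_hill: bool = True,
) -> pd.DataFrame:
    """Fit every compound on a long-format plate (compound, dose, replicate,
    viability); replicates are averaged per dose before fitting."""
    rows = []
    for compound, grp in plate.groupby("compound", sort=False):
        mean = grp.groupby("dose")["viability"].mean().sort_index()
        dr = fit_dose_response(mean.index.to_numpy(), mean.to_numpy(),
                               compound=str(compound), fix_hill=fix_hill)
        rows.append({
            "compound": compound, "top": dr.top, "bottom": dr.bottom,
            "log10_ec50": dr.log10_ec50, "hill": dr.hill,
            "converged": dr.converged, "auc": dr.auc,
        })
    return pd.DataFrame(rows)


def delta_auc(auc_a: pd.Series, auc_b: pd.Series) -> pd.DataFrame:
    """Median-centered delta-AUC ranking: AUC_B - AUC_A per compound.

    Compounds missing in one line are dropped with a warning.  The output is
    sorted ascending by the centered difference, so the compounds the A line
    is most selectively sensitive to come first.
    """
    common = auc_a.index.intersection(auc_b.index)
    dropped = auc_a.index.symmetric_difference(auc_b.index)
    if len(dropped):
        import warnings

        warnings.warn(f"dropping {len(dropped)} compound(s) missing in one line")
    d = (auc_b.loc[common] - auc_a.loc[common]).astype(float)
    centered = d - d.median()
    out = pd.DataFrame({
        "compound": common, "delta_auc": d.to_numpy(),
        "delta_auc_centered": centered.to_numpy(),
    }).sort_values("delta_auc_centered", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
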