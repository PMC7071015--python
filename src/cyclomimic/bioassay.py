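"""Dose-response analysis: plate normalisation and 4PL IC50 fitting.

Absorbance readings (620 nm reporter) are normalised to percent inhibition
between the negative control (reporter response without inhibitor, 0 %)
and the positive/blank baseline (fully inhibited, 100 %), then fitted with
the four-parameter logistic

    y = bottom + (top - bottom) / (1 + (IC50 / x)^hill)

by least squares on the per-well points, so replicate scatter informs the
parameter standard errors.  An IC50 outside the tested dose range is
flagged as extrapolated, mirroring how such values must be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError

__all__ = [
    "DoseResponseFit",
    "normalize_inhibition",
    "fit_4pl",
    "four_parameter_logistic",
]

_REQUIRED_COLS = {"compound", "conc_uM", "a620", "role"}


def four_parameter_logistic(x: np.ndarray, bottom: float, top: float,
                            log_ic50: float, hill: float) -> np.ndarray:
    """4PL response in % inhibition; IC50 parametrised on the log scale."""
    ic50 = np.exp(log_ic50)
    return bottom + (top - bottom) / (1.0 + (ic50 / x) ** hill)


def normalize_inhibition(readings: pd.DataFrame) -> pd.DataFrame:
    """Convert raw 620 nm absorbances into per-well %-inhibition points.

    %inhibition = 100 * (A_neg - A_sample) / (A_neg - A_baseline), where
    A_neg is the negative-control mean and the baseline is the
    positive-control mean when present, else the blank mean.  Returns a tidy
    frame (compound, conc_uM, inhibition_pct) of sample wells plus per-dose
    summary columns via :func:`summarize_inhibition`.
    """
    missing = _REQUIRED_COLS - set(readings.columns)
    if missing:
        raise ValueError(f"readings missing columns: {sorted(missing)}")
    neg = readings.loc[readings.role == "negative", "a620"]
    if neg.empty:
        raise ValueError("no negative-control rows in readings")
    pos = readings.loc[readings.role == "positive", "a620"]
    blank = readings.loc[readings.role == "blank", "a620"]
    if not pos.empty:
        baseline = float(pos.mean())
    elif not blank.empty:
        baseline = float(blank.mean())
    else:
        raise ValueError("need a positive-control or blank baseline")
    a_neg = float(neg.mean())
    span = a_neg - baseline
    if span <= 1e-6 * max(abs(a_neg), 1.0):
        raise FitError(
            f"zero dynamic range: negative control {a_neg:.4f} vs baseline "
            f"{baseline:.4f}")
    samples = readings.loc[readings.role == "sample"].copy()
    samples["inhibition_pct"] = 100.0 * (a_neg - samples["a620"]) / span
    return samples[["compound", "conc_uM", "inhibition_pct"]].reset_index(drop=True)


def summarize_inhibition(points: pd.DataFrame) -> pd.DataFrame:
    """Replicate means with standard errors per (compound, dose)."""
    g = points.groupby(["compound", "conc_uM"])["inhibition_pct"]
    out = g.agg(mean="mean", n="count", sd="std").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters; inhibition in %, IC50 in uM."""

    bottom: float
    top: float
    ic50: float
    hill: float
    se: Tuple[float, float, float, float]   # bottom, top, ic50, hill
    extrapolated: bool
    rss: float
    n_points: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return four_parameter_logistic(np.asarray(x, float), self.bottom,
                                       self.top, np.log(self.ic50), self.hill)


def fit_4pl(points: pd.DataFrame,
            constrain_asymptotes: bool = True,
            bounds_pct: Tuple[float, float] = (-20.0, 120.0)) -> DoseResponseFit:
    """Least-squares 4PL fit of per-well dose/%-inhibition points.

    Requires >= 4 distinct non-zero concentrations.  By default the
    asymptotes are fixed at 0 and 100 % (the "normalised response" model:
    the plate controls already define the response scale, so estimating
    bottom/top from sparse dose points only inflates the IC50 variance);
    with ``constrain_asymptotes=False`` they are free within ``bounds_pct``.
    The Hill slope is unconstrained in sign either way, so agonist-shaped
    data fail loudly instead of fitting spuriously.  Deterministic for
    identical inputs and invariant to row order.
    """
    pts = points.loc[points.conc_uM > 0].sort_values(
        ["conc_uM", "inhibition_pct"], kind="mergesort")
    x = pts["conc_uM"].to_numpy(float)
    y = pts["inhibition_pct"].to_numpy(float)
    if len(np.unique(x)) < 4:
        raise FitError("need >= 4 distinct non-zero concentrations")
    if np.ptp(y) < 1e-9:
        raise FitError("flat response: no dose dependence to fit")

    lo, hi = bounds_pct
    y_lo, y_hi = float(y.min()), float(y.max())
    # initial guesses: anchors from the data, IC50 at the half-response dose
    half = 0.5 * (y_lo + y_hi)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    crossing = xs[np.argmin(np.abs(ys - half))]
    log_lb = np.log(x.min()) - 14.0
    log_ub = np.log(x.max()) + 14.0
    try:
        if constrain_asymptotes:
            def model(xv, log_ic50, hill):
                return four_parameter_logistic(xv, 0.0, 100.0, log_ic50, hill)

            popt2, pcov2 = curve_fit(
                model, x, y, p0=[np.log(crossing), 1.0],
                bounds=([log_lb, -10.0], [log_ub, 10.0]), maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            popt = np.array([0.0, 100.0, popt2[0], popt2[1]])
            perr = np.zeros(4)
            with np.errstate(invalid="ignore"):
                perr[2:] = np.sqrt(np.diag(pcov2))
        else:
            p0 = [max(lo, y_lo), min(hi, y_hi), np.log(crossing), 1.0]
            lbounds = [lo, lo, log_lb, -10.0]
            ubounds = [hi, hi, log_ub, 10.0]
            popt, pcov = curve_fit(four_parameter_logistic, x, y, p0=p0,
                                   bounds=(lbounds, ubounds), maxfev=20000,
                                   xtol=1e-14, ftol=1e-14, gtol=1e-14)
            with np.errstate(invalid="ignore"):
                perr = np.sqrt(np.diag(pcov))
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from None
    resid = y - four_parameter_logistic(x, *popt)
    rss = float(np.sum(resid ** 2))
    ic50 = float(np.exp(popt[2]))
    se_ic50 = float(perr[2] * ic50)       # delta method from log scale
    extrapolated = bool(ic50 < x.min() or ic50 > x.max())
    return DoseResponseFit(
        bottom=float(popt[0]), top=float(popt[1]), ic50=ic50,
        hill=float(popt[3]),
        se=(float(perr[0]), float(perr[1]), se_ic50, float(perr[3])),
        extrapolated=extrapolated, rss=rss, n_points=int(len(x)))
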