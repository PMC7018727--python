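"""Proliferation and drug-sensitivity quantitation from growth time series.

Doubling time is estimated from the log2 of the readout normalised to the
first timepoint: the contiguous log-linear window with positive slope and
maximal r² is selected automatically (wider windows win ties) and the
doubling time is the inverse slope in hours per doubling.

Drug sensitivity follows the area-under-the-curve route: the growth curve
at each concentration is integrated (trapezoid), AUCs are normalised to
percent of the vehicle AUC and fitted with a four-parameter logistic in
log10 concentration, from which the IC50 (µM) is read.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import NoDoseEffectError, NoLogPhaseError

__all__ = ["GrowthCurve", "DoublingTimeFit", "DoseResponseFit",
           "doubling_time", "curve_auc", "fit_dose_response",
           "curves_from_frame"]


@dataclass(frozen=True)
class GrowthCurve:
    """One well's readout time series (green object count or confluency)."""

    timepoints: np.ndarray  # hours, strictly increasing
    values: np.ndarray      # readout, >= 0
    sample: str = ""
    condition: str = ""
    concentration_uM: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("timepoints and values must have equal length")
        if t.size < 2:
            raise ValueError("a growth curve needs >= 2 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "values", v)


def curves_from_frame(df: pd.DataFrame):
    """Yield :class:`GrowthCurve` objects from a long-format growth table."""
    keys = ["sample", "condition", "concentration_uM", "replicate"]
    for (samp, cond, conc, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        yield GrowthCurve(grp["time_h"].to_numpy(), grp["value"].to_numpy(),
                          sample=samp, condition=cond,
                          concentration_uM=float(conc), replicate=int(rep))


@dataclass(frozen=True)
class DoublingTimeFit:
    """Doubling time in hours plus the log-linear window diagnostics."""

    doubling_time_h: float
    window: tuple[float, float]   # (t_start, t_end) hours
    slope: float                  # doublings per hour
    r_squared: float

    def as_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        return d


def doubling_time(curve: GrowthCurve,
                  log_phase: tuple[float, float] | None = None,
                  min_window: int = 5) -> DoublingTimeFit:
    """Estimate the doubling time from the log-phase of a growth curve.

    Values are normalised to the first timepoint and log2-transformed.
    With ``log_phase=None`` the contiguous window of at least
    ``min_window`` points with positive slope maximising r² is selected
    (the widest such window on ties); otherwise the stated time range is
    used. Doubling time is ``1 / slope``.
    """
    t, v = curve.timepoints, curve.values
    if log_phase is not None:
        mask = (t >= log_phase[0]) & (t <= log_phase[1])
        t, v = t[mask], v[mask]
        if t.size < 2:
            raise ValueError("explicit log-phase window holds < 2 points")
    if np.any(v <= 0):
        raise ValueError("non-positive values in the candidate window")
    y = np.log2(v / v[0])

    if log_phase is not None:
        fit = linregress(t, y)
        if fit.slope <= 0:
            raise NoLogPhaseError("no log phase detected (non-positive slope)")
        return DoublingTimeFit(1.0 / fit.slope, (float(t[0]), float(t[-1])),
                               float(fit.slope), float(fit.rvalue ** 2))

    n = t.size
    if n < min_window:
        raise ValueError(f"curve has {n} points; min_window={min_window}")
    best = None  # (r2, width, slope, i, j)
    for i in range(n - min_window + 1):
        for j in range(i + min_window - 1, n):
            fit = linregress(t[i:j + 1], y[i:j + 1])
            if fit.slope <= 0:
                continue
            r2 = fit.rvalue ** 2
            key = (round(r2, 12), j - i)
            if best is None or key > best[0]:
                best = (key, fit.slope, i, j)
    if best is None:
        raise NoLogPhaseError("no log phase detected (no positive-slope window)")
    _, slope, i, j = best
    fit = linregress(t[i:j + 1], y[i:j + 1])
    return DoublingTimeFit(1.0 / slope, (float(t[i]), float(t[j])),
                           float(slope), float(fit.rvalue ** 2))


def curve_auc(curve: GrowthCurve, t_range: tuple[float, float] | None = None) -> float:
    """Trapezoidal area under the growth curve over ``t_range`` (hours).

    The range must lie within the observed time span; curve values at the
    range endpoints are linearly interpolated when they fall between
    samples.
    """
    t, v = curve.timepoints, curve.values
    if t_range is None:
        t_range = (float(t[0]), float(t[-1]))
    lo, hi = t_range
    if lo < t[0] or hi > t[-1] or lo >= hi:
        raise ValueError(f"t_range {t_range} outside observed span ({t[0]}, {t[-1]})")
    inner = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inner], [hi]))
    vv = np.concatenate(([np.interp(lo, t, v)], v[inner], [np.interp(hi, t, v)]))
    return float(np.trapezoid(vv, tt))


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit of percent-of-vehicle AUC vs concentration."""

    top: float
    bottom: float
    hill: float
    ic50_uM: float | None
    converged: bool
    residual: float

    def as_dict(self) -> dict:
        return asdict(self)


def _four_pl(logc: np.ndarray, top: float, bottom: float, hill: float,
             log_ic50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_dose_response(points, vehicle_auc: float,
                      min_span_pct: float = 10.0) -> DoseResponseFit:
    """Fit a four-parameter logistic dose-response to (concentration, AUC).

    AUCs are normalised to percent of ``vehicle_auc``; the 4PL is fitted by
    nonlinear least squares in log10 concentration with bottom bounded at
    0 and a sign-free hill slope. The vehicle itself is not a fit point.

    Raises
    ------
    NoDoseEffectError
        If the response span is below ``min_span_pct`` percent of vehicle.
    """
    pts = [(float(c), float(a)) for c, a in points]
    if any(c <= 0 for c, _ in pts):
        raise ValueError("concentrations must be positive (vehicle is not a fit point)")
    if vehicle_auc <= 0:
        raise ValueError("vehicle_auc must be positive")
    if len({c for c, _ in pts}) < 4:
        raise ValueError("need >= 4 distinct concentrations")

    logc = np.log10([c for c, _ in pts])
    y = 100.0 * np.array([a for _, a in pts]) / vehicle_auc
    span = y.max() - y.min()
    if span < min_span_pct:
        raise NoDoseEffectError(
            f"no dose effect: response span {span:.1f}% < {min_span_pct}% of vehicle")

    half = (y.max() + y.min()) / 2.0
    log_ic50_0 = logc[np.argmin(np.abs(y - half))]
    p0 = [y.max(), y.min(), 1.0, log_ic50_0]
    bounds = ([0.0, 0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(_four_pl, logc, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        return DoseResponseFit(top=float("nan"), bottom=float("nan"),
                               hill=float("nan"), ic50_uM=None,
                               converged=False, residual=float("nan"))
    top, bottom, hill, log_ic50 = popt
    resid = float(np.sum((_four_pl(logc, *popt) - y) ** 2))
    if bottom > top:
        # mirrored solution: swap and flip the hill sign
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(top=float(top), bottom=float(bottom), hill=float(hill),
                           ic50_uM=float(10.0 ** log_ic50), converged=True,
                           residual=resid)
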