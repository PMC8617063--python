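"""Plasma coagulation trace analysis: clot waveforms and thrombograms.

Two global coagulation read-outs are handled here:

* Clot waveform analysis (CWA): the light-transmittance curve recorded
  during an aPTT measurement is differentiated; the minima of the
  first, second and third derivatives (min1, min2, min3) are proxies
  for thrombin, prothrombinase and tenase activity respectively.
* Thrombin-generation test (TGT): a thrombogram (thrombin
  concentration vs time) is summarised by lag-time (LT), time-to-peak
  (TTpeak), peak thrombin, endogenous thrombin potential (ETP, the
  area under the curve) and the velocity index (VI).

Anticoagulant intensity gradients are quantified with the log-log
dose-response line Y = 10^(m*log10(X) + C), whose slope m measures how
steeply a TGT/CWA parameter moves with anticoagulant dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ._base import FitResultsBase, summary_table

__all__ = [
    "CWAResult",
    "cwa_analyze",
    "TGTParams",
    "tgt_parameters",
    "fold_change_series",
    "LogLogModel",
    "LogLogResults",
    "gradient_ratio",
]


# ---------------------------------------------------------------------------
# clot waveform analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CWAResult:
    """Derivative minima of a clotting transmittance curve.

    min1 (%/s) is the most negative slope of the transmittance fall,
    min2 (%/s^2) and min3 (%/s^3) the minima of the second and third
    derivatives.  ``clot_time`` is the time of min1 — the moment of the
    maximum rate of transmittance fall (the analyzer's proprietary
    threshold rule is unpublished, so this package uses the min1 time
    and documents it).  ``clot_detected=False`` marks a flat trace.
    """

    clot_detected: bool
    clot_time_s: float = np.nan
    min1: float = np.nan
    min1_time_s: float = np.nan
    min2: float = np.nan
    min2_time_s: float = np.nan
    min3: float = np.nan
    min3_time_s: float = np.nan


def cwa_analyze(
    time_s,
    transmittance_pct,
    smooth_window: int | None = None,
    polyorder: int = 5,
    min_drop_pct: float = 2.0,
) -> CWAResult:
    """Extract min1/min2/min3 from a clot waveform.

    Derivatives are estimated with Savitzky-Golay local-polynomial
    filters (window ``smooth_window`` samples, default 11) rather than
    raw finite differences, which amplify noise at the second and third
    order.  A trace whose total transmittance drop is below
    ``min_drop_pct`` is reported as a no-clot result, not an error.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(transmittance_pct, dtype=float)
    if t.size != y.size:
        raise ValueError("time and transmittance lengths differ")
    if t.size < 50:
        raise ValueError("need >= 50 samples for derivative analysis")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    if (dt.max() - dt.min()) > 0.05 * dt.mean():
        raise ValueError("sampling must be uniform or near-uniform")
    step = float(dt.mean())

    if (y.max() - y.min()) < min_drop_pct:
        return CWAResult(clot_detected=False)

    win = 11 if smooth_window is None else int(smooth_window)
    if win % 2 == 0:
        win += 1
    win = min(win, t.size if t.size % 2 else t.size - 1)
    po = min(polyorder, win - 1)
    if po < 4:
        raise ValueError("polyorder must be >= 4 to support third derivatives")

    d1 = savgol_filter(y, win, po, deriv=1, delta=step)
    d2 = savgol_filter(y, win, po, deriv=2, delta=step)
    d3 = savgol_filter(y, win, po, deriv=3, delta=step)

    # exclude the filter's edge region where the local polynomial is
    # one-sided and derivative estimates degrade
    edge = win // 2
    sl = slice(edge, t.size - edge)

    def _argmin(d):
        i = int(np.argmin(d[sl])) + edge
        return float(d[i]), float(t[i])

    m1, t1 = _argmin(d1)
    m2, t2 = _argmin(d2)
    m3, t3 = _argmin(d3)
    return CWAResult(
        clot_detected=True,
        clot_time_s=t1,
        min1=m1, min1_time_s=t1,
        min2=m2, min2_time_s=t2,
        min3=m3, min3_time_s=t3,
    )


# ---------------------------------------------------------------------------
# thrombogram parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TGTParams:
    """Scalar summary of a single-pulse thrombogram."""

    lag_time_min: float
    time_to_peak_min: float
    peak_nM: float
    etp_nM_min: float
    velocity_index_nM_per_min: float
    vi_defined: bool = True


def tgt_parameters(
    time_min,
    thrombin_nM,
    lag_fraction: float = 0.1,
    lag_mode: str = "fraction",
    lag_threshold_nM: float = 2.0,
) -> TGTParams:
    """Extract LT, TTpeak, peak, ETP and VI from a thrombogram.

    * peak = maximum thrombin; TTpeak = its time.
    * LT = first crossing of ``lag_fraction * peak`` (default 10%), by
      linear interpolation between samples so grid alignment does not
      bias the estimate.  ``lag_mode="threshold"`` uses the fixed
      Thrombinoscope-style 2 nM crossing instead.
    * ETP = trapezoidal area under the curve (nM*min).
    * VI = peak / (TTpeak - LT); flagged undefined when TTpeak == LT.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(thrombin_nM, dtype=float)
    if t.size != y.size:
        raise ValueError("time and thrombin lengths differ")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if np.any(y < -1e-9):
        raise ValueError("thrombin concentrations must be non-negative")
    peak = float(y.max())
    if peak <= 0:
        raise ValueError("all-zero thrombogram: no thrombin generated")
    ip = int(np.argmax(y))
    tt_peak = float(t[ip])

    if lag_mode == "fraction":
        thresh = lag_fraction * peak
    elif lag_mode == "threshold":
        thresh = lag_threshold_nM
    else:
        raise ValueError("lag_mode must be 'fraction' or 'threshold'")

    above = np.nonzero(y > thresh)[0]
    if above.size == 0:
        raise ValueError("curve never exceeds the lag threshold")
    i = int(above[0])
    if i == 0:
        lt = float(t[0])
    else:
        # linear interpolation of the crossing between samples i-1 and i
        y0, y1 = y[i - 1], y[i]
        lt = float(t[i - 1] + (thresh - y0) / (y1 - y0) * (t[i] - t[i - 1]))

    etp = float(np.trapezoid(y, t))
    span = tt_peak - lt
    if span <= 0:
        return TGTParams(lt, tt_peak, peak, etp, np.nan, vi_defined=False)
    return TGTParams(lt, tt_peak, peak, etp, peak / span, vi_defined=True)


# ---------------------------------------------------------------------------
# dose-response intensity gradients
# ---------------------------------------------------------------------------

def fold_change_series(values, vehicle_value: float):
    """Normalise a dose series to its vehicle control (value / vehicle)."""
    if vehicle_value <= 0:
        raise ValueError("vehicle value must be positive")
    return np.asarray(values, dtype=float) / float(vehicle_value)


class LogLogResults(FitResultsBase):
    """Fitted log-log line Y = 10^(m*log10 X + C)."""

    def __init__(self, m, m_se, C, C_se, r_squared, nobs, parameter_name):
        self.m = m
        self.m_se = m_se
        self.C = C
        self.C_se = C_se
        self.r_squared = r_squared
        self.nobs = nobs
        self.parameter_name = parameter_name

    def predict(self, doses):
        x = np.log10(np.asarray(doses, dtype=float))
        return 10.0 ** (self.m * x + self.C)

    def summary(self) -> str:
        rows = [("m (slope, log10-log10)", self.m, self.m_se),
                ("C (intercept)", self.C, self.C_se)]
        extra = [("parameter", self.parameter_name or "-"),
                 ("r^2", f"{self.r_squared:.4f}"),
                 ("n doses", f"{self.nobs}")]
        return summary_table("Log-log intensity gradient fit", rows, extra)


class LogLogModel:
    """OLS of log10(value) on log10(dose).

    The slope m measures how sharply an anticoagulant-intensity
    parameter (LT, TTpeak, peak, ETP, VI or a CWA minimum) changes with
    dose; shallow slopes indicate a gradual, forgiving dose-response.
    Fitting fold-change-normalised values shifts only the intercept C,
    never the slope.
    """

    def __init__(self, doses, values, parameter_name: str = ""):
        self.doses = np.asarray(doses, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.doses.size != self.values.size:
            raise ValueError("doses and values lengths differ")
        if np.unique(self.doses).size < 3:
            raise ValueError("need >= 3 distinct dose levels")
        if np.any(self.doses <= 0) or np.any(self.values <= 0):
            raise ValueError("doses and values must be positive for log-log fitting")
        self.parameter_name = parameter_name

    def fit(self) -> LogLogResults:
        x = np.log10(self.doses)
        y = np.log10(self.values)
        n = x.size
        (m, c), cov = np.polyfit(x, y, 1, cov=True) if n > 2 else (np.polyfit(x, y, 1), None)
        fitted = m * x + c
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        if cov is not None:
            m_se, c_se = np.sqrt(np.diag(cov))
        else:
            m_se = c_se = np.nan
        return LogLogResults(float(m), float(m_se), float(c), float(c_se),
                             float(r2), int(n), self.parameter_name)


def gradient_ratio(fit_a: LogLogResults, fit_b: LogLogResults) -> float:
    """|m_a| / |m_b| between two log-log fits of the same parameter."""
    if fit_a.parameter_name != fit_b.parameter_name:
        raise ValueError("gradient ratio requires fits of the same parameter")
    if fit_b.m == 0:
        raise ValueError("denominator slope is zero")
    return abs(fit_a.m) / abs(fit_b.m)
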