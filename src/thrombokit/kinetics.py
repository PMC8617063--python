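"""Tight-binding enzyme inhibition kinetics for chromogenic protease assays.

This module covers the kinetic analysis chain used to characterise
fast, tight-binding direct thrombin inhibitors:

* steady-state velocities from linear progress curves (absorbance at
  405 nm vs. time, p-nitroaniline release from a chromogenic substrate
  such as S2238),
* the Morrison tight-binding velocity equation and its nonlinear fit
  for the apparent inhibition constant Ki',
* the competitive-mode regression Ki'(S) = Ki * (1 + S/Km) that yields
  the true Ki from a substrate-concentration series,
* four-parameter logistic IC50 fits and the non-competitive Ki = IC50
  identity,
* percent-inhibition arithmetic, selectivity-panel fold bounds and
  Ki fold-potency ratios.

Units follow the field's conventions: enzyme and inhibitor
concentrations in nM, substrate in µM, reported Ki and Ki' in pM,
velocities in AU/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
import statsmodels.api as sm

from ._base import FitResultsBase, summary_table

__all__ = [
    "ProgressCurve",
    "VelocityEstimate",
    "InhibitionSeries",
    "estimate_velocity",
    "fractional_velocities",
    "morrison_velocity",
    "MorrisonModel",
    "MorrisonResults",
    "CompetitiveKiModel",
    "CompetitiveKiResults",
    "LogisticIC50Model",
    "LogisticIC50Results",
    "NoncompetitiveKi",
    "noncompetitive_ki",
    "percent_inhibition",
    "selectivity_fold",
    "SelectivityFold",
    "ki_fold_ratio",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ProgressCurve:
    """One chromogenic-substrate kinetic read.

    Parameters
    ----------
    time_s : array
        Sampling times in seconds, strictly increasing.
    absorbance_au : array
        Absorbance at 405 nm, in absorbance units (AU).
    Et_nM : float
        Total enzyme concentration (> 0).
    It_nM : float
        Total inhibitor concentration (>= 0).
    S_uM : float
        Substrate concentration (> 0).
    """

    time_s: np.ndarray
    absorbance_au: np.ndarray
    Et_nM: float
    It_nM: float = 0.0
    S_uM: float = 100.0
    inhibitor_id: str = ""
    protease_id: str = "thrombin"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance_au = np.asarray(self.absorbance_au, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size != self.absorbance_au.size:
            raise ValueError("time and absorbance must be 1-D and equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.Et_nM <= 0:
            raise ValueError("enzyme concentration Et must be positive")
        if self.It_nM < 0:
            raise ValueError("inhibitor concentration It must be non-negative")
        if self.S_uM <= 0:
            raise ValueError("substrate concentration S must be positive")


@dataclass(frozen=True)
class VelocityEstimate:
    """Steady-state velocity from a linear progress-curve window."""

    v_au_per_min: float
    r_squared: float
    window_s: tuple[float, float]
    n_points: int


@dataclass
class InhibitionSeries:
    """Fractional velocities vs/vo across inhibitor concentrations.

    ``points`` holds (It_nM, vs/vo) pairs including the (0, 1.0)
    reference.  Fractional velocities above 1 are permitted (activation).
    """

    Et_nM: float
    S_uM: float
    It_nM: np.ndarray
    fractional_velocity: np.ndarray
    inhibitor_id: str = ""

    def __post_init__(self) -> None:
        self.It_nM = np.asarray(self.It_nM, dtype=float)
        self.fractional_velocity = np.asarray(self.fractional_velocity, dtype=float)
        if self.It_nM.size != self.fractional_velocity.size:
            raise ValueError("It and fractional velocity lengths differ")
        if np.any(self.fractional_velocity < 0):
            raise ValueError("fractional velocities must be non-negative")
        if self.Et_nM <= 0:
            raise ValueError("Et must be positive")


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------

def estimate_velocity(
    curve: ProgressCurve,
    window_s: tuple[float, float] | None = None,
) -> VelocityEstimate:
    """Least-squares slope of a progress curve, in AU/min.

    The default window is the full trace: the assay relies on linear
    ("fast-binding") progress curves, so no burst-phase handling is
    attempted.  ``r_squared`` is reported as a linearity diagnostic.
    """
    t, a = curve.time_s, curve.absorbance_au
    if window_s is not None:
        lo, hi = window_s
        if lo >= hi:
            raise ValueError("window must satisfy lo < hi")
        if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise ValueError("window outside trace span")
        mask = (t >= lo) & (t <= hi)
        t, a = t[mask], a[mask]
    else:
        window_s = (float(t[0]), float(t[-1]))
    if t.size < 5:
        raise ValueError("need at least 5 samples in the fit window")
    tm = t / 60.0  # minutes
    slope, intercept = np.polyfit(tm, a, 1)
    fitted = slope * tm + intercept
    ss_res = float(np.sum((a - fitted) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot <= 0.0 or ss_res <= 1e-300:
        r2 = 1.0 if ss_res <= max(1e-30, 1e-12 * max(ss_tot, 1.0)) else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return VelocityEstimate(float(slope), r2, (float(window_s[0]), float(window_s[1])), int(t.size))


def fractional_velocities(
    curves: Sequence[ProgressCurve],
    window_s: tuple[float, float] | None = None,
) -> InhibitionSeries:
    """Build an inhibition series vs/vo from grouped progress curves.

    Exactly one curve must have It = 0 (the uninhibited reference); all
    curves must share Et and S.  The reference point (0, 1.0) is
    included in the output.
    """
    if not curves:
        raise ValueError("no curves supplied")
    refs = [c for c in curves if c.It_nM == 0.0]
    if len(refs) != 1:
        raise ValueError("exactly one It=0 reference curve required per group")
    ref = refs[0]
    for c in curves:
        if not (np.isclose(c.Et_nM, ref.Et_nM) and np.isclose(c.S_uM, ref.S_uM)):
            raise ValueError("all curves in a group must share Et and S")
    v0 = estimate_velocity(ref, window_s).v_au_per_min
    if v0 <= 0:
        raise ValueError("uninhibited velocity v(0) must be positive")
    its, fvs = [], []
    for c in curves:
        v = estimate_velocity(c, window_s).v_au_per_min
        its.append(c.It_nM)
        fvs.append(1.0 if c is ref else v / v0)
    order = np.argsort(its)
    return InhibitionSeries(
        Et_nM=ref.Et_nM,
        S_uM=ref.S_uM,
        It_nM=np.asarray(its)[order],
        fractional_velocity=np.asarray(fvs)[order],
        inhibitor_id=ref.inhibitor_id or curves[-1].inhibitor_id,
    )


# ---------------------------------------------------------------------------
# Morrison tight-binding velocity and fit
# ---------------------------------------------------------------------------

def morrison_velocity(ki_prime, it, et, vo=1.0):
    """Morrison steady-state velocity for a tight-binding inhibitor.

    vs = (vo / 2 Et) * ( sqrt((Ki' + It - Et)^2 + 4 Ki' Et) - (Ki' + It - Et) )

    All concentrations must share one unit (nM throughout this package).
    In the tight-binding regime It ~ Et, free inhibitor is depleted by
    binding, so the simple [I]-based isotherm does not apply; this
    quadratic solution accounts for that depletion.  ``vs`` lies in
    [0, vo] and reduces to ``vo`` at It = 0.
    """
    ki_prime = np.asarray(ki_prime, dtype=float)
    it = np.asarray(it, dtype=float)
    if np.any(np.asarray(et) <= 0):
        raise ValueError("Et must be positive")
    if np.any(ki_prime < 0) or np.any(it < 0):
        raise ValueError("Ki' and It must be non-negative")
    b = ki_prime + it - et
    root = np.sqrt(b * b + 4.0 * ki_prime * et)
    # conjugate form for b > 0 avoids catastrophic cancellation when
    # Ki' >> Et (root - b is then a difference of nearly equal numbers)
    out = np.where(
        b > 0,
        vo * 2.0 * ki_prime / np.where(root + b > 0, root + b, np.inf),
        (vo / (2.0 * et)) * (root - b),
    )
    return out if out.ndim else float(out)


class MorrisonResults(FitResultsBase):
    """Morrison fit results: apparent Ki' (pM) with standard error."""

    def __init__(self, ki_prime_pM, ki_prime_se_pM, vo, vo_se, rss, nobs, series):
        self.ki_prime_pM = ki_prime_pM
        self.ki_prime_se_pM = ki_prime_se_pM
        self.vo = vo
        self.vo_se = vo_se
        self.rss = rss
        self.nobs = nobs
        self.series = series

    @property
    def tight_binding_regime(self) -> bool:
        """True when fitted Ki' is far below Et (Ki' < Et / 10)."""
        return self.ki_prime_pM < 0.1 * self.series.Et_nM * 1e3

    def predict(self, it_nM):
        return morrison_velocity(self.ki_prime_pM / 1e3, it_nM, self.series.Et_nM, self.vo)

    def summary(self) -> str:
        rows = [
            ("Ki' (pM)", self.ki_prime_pM, self.ki_prime_se_pM),
            ("vo (fractional)", self.vo, self.vo_se),
        ]
        extra = [
            ("Et (nM)", f"{self.series.Et_nM:g}"),
            ("S (uM)", f"{self.series.S_uM:g}"),
            ("RSS", f"{self.rss:.3e}"),
            ("n", f"{self.nobs}"),
            ("tight-binding regime", str(self.tight_binding_regime)),
        ]
        return summary_table("Morrison tight-binding fit", rows, extra)


class MorrisonModel:
    """Nonlinear least-squares fit of the Morrison velocity equation.

    Parameters
    ----------
    series : InhibitionSeries
        Fractional velocities vs/vo against total inhibitor (nM),
        including the uninhibited reference point.
    vo_mode : {"fixed", "fitted"}
        "fixed" (default) pins vo to the measured It=0 velocity, i.e.
        1.0 on the fractional scale, matching assays where vo is
        measured directly.  "fitted" co-estimates vo for robustness
        studies.

    The fit is performed in log10(Ki') to enforce positivity; standard
    errors come from the Jacobian-based covariance at the optimum,
    propagated back to the linear pM scale.
    """

    def __init__(self, series: InhibitionSeries, vo_mode: str = "fixed"):
        if vo_mode not in ("fixed", "fitted"):
            raise ValueError("vo_mode must be 'fixed' or 'fitted'")
        if series.It_nM.size < 4:
            raise ValueError("tight-binding fit needs >= 4 inhibitor levels")
        if series.It_nM.max() <= series.Et_nM or series.It_nM[series.It_nM > 0].min() >= series.Et_nM:
            # informative but non-fatal: design should bracket Et
            pass
        if np.allclose(series.fractional_velocity, series.fractional_velocity[0]):
            raise ValueError("degenerate input: all fractional velocities identical")
        self.series = series
        self.vo_mode = vo_mode

    def fit(self) -> MorrisonResults:
        it = self.series.It_nM
        fv = self.series.fractional_velocity
        et = self.series.Et_nM

        def resid(theta):
            # clip the exponent: keeps the optimizer's exploratory steps
            # finite without constraining any plausible Ki'
            ki_nM = 10.0 ** min(max(theta[0], -12.0), 12.0)
            vo = theta[1] if self.vo_mode == "fitted" else 1.0
            return morrison_velocity(ki_nM, it, et, vo) - fv

        # coarse init from the fractional velocity nearest 0.5
        pos = it > 0
        if np.any(pos):
            i = np.argmin(np.abs(fv[pos] - 0.5))
            it_half = it[pos][i]
            ki0 = max(abs(it_half - et / 2.0), 1e-6 * et)
        else:
            ki0 = et
        x0 = [np.log10(ki0)] + ([1.0] if self.vo_mode == "fitted" else [])
        best = None
        for shift in (0.0, -2.0, 2.0, -4.0):
            start = list(x0)
            start[0] += shift
            sol = optimize.least_squares(resid, start, method="lm", xtol=1e-15, ftol=1e-15)
            if best is None or sol.cost < best.cost - 1e-18:
                best = sol
        sol = best
        if not sol.success:
            raise RuntimeError(f"Morrison fit did not converge: {sol.message}")
        ki_nM = 10.0 ** min(max(sol.x[0], -12.0), 12.0)
        vo = float(sol.x[1]) if self.vo_mode == "fitted" else 1.0

        # covariance from J^T J
        dof = max(it.size - sol.x.size, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
            se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se_log = np.full(sol.x.size, np.nan)
        # delta method: d(ki)/d(log10 ki) = ki * ln 10
        ki_se_nM = ki_nM * np.log(10.0) * se_log[0]
        vo_se = float(se_log[1]) if self.vo_mode == "fitted" else 0.0
        return MorrisonResults(
            ki_prime_pM=float(ki_nM * 1e3),
            ki_prime_se_pM=float(ki_se_nM * 1e3),
            vo=vo,
            vo_se=vo_se,
            rss=float(2.0 * sol.cost),
            nobs=int(it.size),
            series=self.series,
        )


# ---------------------------------------------------------------------------
# competitive-mode Ki from a substrate series
# ---------------------------------------------------------------------------

class CompetitiveKiResults(FitResultsBase):
    """Ki'(S) regression: intercept = true Ki, Km = intercept/slope."""

    def __init__(self, ki_pM, ki_se_pM, slope, slope_se, km_uM, r_squared, mode_call, nobs):
        self.ki_pM = ki_pM
        self.ki_se_pM = ki_se_pM
        self.slope_pM_per_uM = slope
        self.slope_se = slope_se
        self.km_uM = km_uM
        self.linearity_r2 = r_squared
        self.mode_call = mode_call
        self.nobs = nobs

    def summary(self) -> str:
        rows = [
            ("Ki (pM, intercept)", self.ki_pM, self.ki_se_pM),
            ("slope (pM/uM)", self.slope_pM_per_uM, self.slope_se),
        ]
        extra = [
            ("Km derived (uM)", f"{self.km_uM:.4g}" if np.isfinite(self.km_uM) else "undefined"),
            ("linearity r^2", f"{self.linearity_r2:.4f}"),
            ("mode call", self.mode_call),
            ("n substrate levels", f"{self.nobs}"),
        ]
        return summary_table("Competitive Ki from Ki'(S) series", rows, extra)


class CompetitiveKiModel:
    """Linear regression of apparent Ki' on substrate concentration.

    For a competitive inhibitor Ki'(S) = Ki * (1 + S/Km): the intercept
    at S = 0 is the true Ki and Km = intercept/slope.  The regression is
    inverse-variance weighted when Ki' standard errors are supplied,
    unweighted otherwise.  The mechanism call is
    ``competitive_consistent`` when the regression r^2 meets the
    linearity threshold (default 0.9) and the slope is meaningfully
    positive; a flat series (slope ~ 0 relative to Ki'ravel) leaves Km
    undefined, the signature of a non-competitive pattern.
    """

    def __init__(
        self,
        S_uM: Sequence[float],
        ki_prime_pM: Sequence[float],
        ki_prime_se_pM: Sequence[float] | None = None,
        r2_threshold: float = 0.9,
    ):
        self.S = np.asarray(S_uM, dtype=float)
        self.kip = np.asarray(ki_prime_pM, dtype=float)
        self.se = None if ki_prime_se_pM is None else np.asarray(ki_prime_se_pM, dtype=float)
        if np.unique(self.S).size < 3:
            raise ValueError("need >= 3 distinct substrate concentrations")
        if np.any(self.S <= 0) or np.any(self.kip <= 0):
            raise ValueError("substrate and Ki' values must be positive")
        if self.se is not None and np.any(self.se <= 0):
            raise ValueError("Ki' standard errors must be positive")
        self.r2_threshold = r2_threshold

    def fit(self) -> CompetitiveKiResults:
        X = sm.add_constant(self.S)
        if self.se is not None:
            res = sm.WLS(self.kip, X, weights=1.0 / self.se**2).fit()
        else:
            res = sm.OLS(self.kip, X).fit()
        intercept, slope = res.params
        se_i, se_s = res.bse
        # r^2 computed on the unweighted scale as the linearity diagnostic
        fitted = intercept + slope * self.S
        ss_res = float(np.sum((self.kip - fitted) ** 2))
        ss_tot = float(np.sum((self.kip - self.kip.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        flat = abs(slope) * (self.S.max() - self.S.min()) < 1e-6 * max(self.kip.mean(), 1e-300)
        if flat:
            mode = "nonlinear"
            km = np.nan
        else:
            km = intercept / slope
            mode = "competitive_consistent" if r2 >= self.r2_threshold and slope > 0 else "nonlinear"
        if mode == "competitive_consistent" and intercept <= 0:
            raise ValueError("non-positive fitted intercept: Ki undefined")
        return CompetitiveKiResults(
            ki_pM=float(intercept),
            ki_se_pM=float(se_i),
            slope=float(slope),
            slope_se=float(se_s),
            km_uM=float(km),
            r_squared=float(r2),
            mode_call=mode,
            nobs=int(self.S.size),
        )


# ---------------------------------------------------------------------------
# logistic IC50
# ---------------------------------------------------------------------------

class LogisticIC50Results(FitResultsBase):
    def __init__(self, A1, A2, x0, H, ic50, rss, nobs, ses):
        self.A1 = A1
        self.A2 = A2
        self.x0 = x0
        self.H = H
        self.ic50 = ic50
        self.rss = rss
        self.nobs = nobs
        self.bse = ses  # dict

    def predict(self, conc):
        x = np.log10(np.asarray(conc, dtype=float))
        return self.A2 + (self.A1 - self.A2) / (1.0 + 10.0 ** (self.H * (x - self.x0)))

    def summary(self) -> str:
        rows = [
            ("IC50", self.ic50, self.bse.get("ic50", np.nan)),
            ("A1 (left asymptote, %)", self.A1, self.bse.get("A1", np.nan)),
            ("A2 (right asymptote, %)", self.A2, self.bse.get("A2", np.nan)),
            ("H (slope)", self.H, self.bse.get("H", np.nan)),
        ]
        extra = [("x0 = log10 IC50", f"{self.x0:.4f}"), ("RSS", f"{self.rss:.3e}"), ("n", f"{self.nobs}")]
        return summary_table("Logistic IC50 fit", rows, extra)


class LogisticIC50Model:
    """Four-parameter logistic dose-response fit on the log10-dose axis.

    y = A2 + (A1 - A2) / (1 + 10^(H*(x - x0))),  x = log10(concentration)

    where y is percent inhibition, A1/A2 the left/right asymptotes, x0
    the inflection point and H the slope; IC50 = 10^x0.  At x = x0 the
    curve passes through (A1+A2)/2.  ``constrained=True`` pins the
    asymptotes to A1=0, A2=100, the natural bounds for % inhibition.
    """

    def __init__(self, conc, response_pct, constrained: bool = False):
        self.conc = np.asarray(conc, dtype=float)
        self.y = np.asarray(response_pct, dtype=float)
        if self.conc.size != self.y.size:
            raise ValueError("conc and response lengths differ")
        if np.unique(self.conc).size < 4:
            raise ValueError("need >= 4 dose levels spanning the inflection")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.allclose(self.y, self.y[0]):
            raise ValueError("responses constant: IC50 unidentifiable")
        self.constrained = constrained

    def fit(self) -> LogisticIC50Results:
        x = np.log10(self.conc)
        y = self.y

        if self.constrained:
            def model(theta):
                x0, h = theta
                return 100.0 - 100.0 / (1.0 + 10.0 ** (h * (x - x0)))
            x0_init = [float(np.interp(50.0, np.sort(y), x[np.argsort(y)])), 1.0]
            names = ["x0", "H"]
        else:
            def model(theta):
                a1, a2, x0, h = theta
                return a2 + (a1 - a2) / (1.0 + 10.0 ** (h * (x - x0)))
            x0_init = [float(y.min()), float(y.max()),
                       float(np.median(x)), 1.0]
            names = ["A1", "A2", "x0", "H"]

        def resid(theta):
            return model(theta) - y

        best = None
        for h0 in (1.0, 2.0, 0.5, -1.0):
            start = list(x0_init)
            start[-1] = h0
            sol = optimize.least_squares(resid, start, method="lm", xtol=1e-15, ftol=1e-15, max_nfev=20000)
            if best is None or sol.cost < best.cost - 1e-18:
                best = sol
        sol = best
        if not sol.success:
            raise RuntimeError(f"logistic fit did not converge: {sol.message}")
        if self.constrained:
            a1, a2 = 0.0, 100.0
            x0, h = sol.x
        else:
            a1, a2, x0, h = sol.x
        if np.isclose(a1, a2):
            raise RuntimeError("degenerate logistic fit: equal asymptotes")
        dof = max(y.size - sol.x.size, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * s2
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(sol.x.size, np.nan)
        ses = dict(zip(names, se))
        ic50 = 10.0 ** x0
        ses["ic50"] = ic50 * np.log(10.0) * ses.get("x0", np.nan)
        return LogisticIC50Results(
            A1=float(a1), A2=float(a2), x0=float(x0), H=float(h),
            ic50=float(ic50), rss=float(2.0 * sol.cost), nobs=int(y.size), ses=ses,
        )


@dataclass(frozen=True)
class NoncompetitiveKi:
    """A Ki obtained via the non-competitive identity Ki = IC50."""

    ki: float
    unit: str = "nM"
    mode: str = "non-competitive (Ki = IC50)"

    def to_dict(self) -> dict:
        return {"ki": self.ki, "unit": self.unit, "mode": self.mode}


def noncompetitive_ki(fit: LogisticIC50Results, unit: str = "nM") -> NoncompetitiveKi:
    """For non-competitive inhibition the inhibitory constant equals IC50.

    Returns the fitted IC50 relabelled as Ki, annotated with the mode so
    reports preserve the provenance of the number.
    """
    return NoncompetitiveKi(ki=float(fit.ic50), unit=unit)


# ---------------------------------------------------------------------------
# panel arithmetic
# ---------------------------------------------------------------------------

def percent_inhibition(v_inhibited: float, v_control: float) -> float:
    """100 * (1 - v_i / v_0).  Negative values denote activation."""
    if v_control <= 0:
        raise ValueError("control velocity must be positive")
    return 100.0 * (1.0 - v_inhibited / v_control)


@dataclass(frozen=True)
class SelectivityFold:
    fold: float
    target_conc_nM: float
    off_target_conc_nM: float
    limiting_off_target: str
    selective: bool

    def __float__(self) -> float:
        return self.fold


def selectivity_fold(
    panel: pd.DataFrame,
    target: str,
    threshold_pct: float = 20.0,
) -> SelectivityFold:
    """Lower bound on target selectivity from a protease panel.

    ``panel`` needs columns ``protease_id``, ``inhibitor_conc_nM`` and
    ``pct_inhibition``.  The bound is the lowest off-target
    concentration at which inhibition stays below ``threshold_pct``
    divided by the highest target concentration with inhibition at or
    above the threshold -- the most conservative ratio the data
    support.  ``fold < 1`` (an off-target hit below the target's active
    concentration) is flagged non-selective.
    """
    required = {"protease_id", "inhibitor_conc_nM", "pct_inhibition"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    tgt = panel[panel["protease_id"] == target]
    off = panel[panel["protease_id"] != target]
    if tgt.empty:
        raise ValueError(f"target protease {target!r} absent from panel")
    if off.empty:
        raise ValueError("panel has no off-target rows")
    tgt_active = tgt[tgt["pct_inhibition"] >= threshold_pct]
    off_quiet = off[off["pct_inhibition"] < threshold_pct]
    if tgt_active.empty:
        raise ValueError("target never reaches the inhibition threshold")
    if off_quiet.empty:
        raise ValueError("every off-target row exceeds the inhibition threshold")
    tc = float(tgt_active["inhibitor_conc_nM"].max())
    idx = off_quiet["inhibitor_conc_nM"].idxmin()
    oc = float(off_quiet.loc[idx, "inhibitor_conc_nM"])
    limiting = str(off_quiet.loc[idx, "protease_id"])
    fold = oc / tc
    return SelectivityFold(fold=fold, target_conc_nM=tc, off_target_conc_nM=oc,
                           limiting_off_target=limiting, selective=fold >= 1.0)


def ki_fold_ratio(ki_a: float, ki_b: float, rounding: str = "none") -> float:
    """Fold-potency ratio ki_a / ki_b between two inhibition constants.

    ``rounding="nearest_integer"`` reports the conventional integer fold
    (e.g. a 1780 pM vs 4.0 pM pair reads as 445-fold).
    """
    if ki_a <= 0 or ki_b <= 0:
        raise ValueError("Ki values must be positive")
    if rounding not in ("none", "nearest_integer"):
        raise ValueError("rounding must be 'none' or 'nearest_integer'")
    fold = ki_a / ki_b
    return float(round(fold)) if rounding == "nearest_integer" else float(fold)
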