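"""In-vivo pharmacodynamics: censored dose-response-time fitting.

Rodent efficacy/safety experiments record a *response time* — the time
to complete arterial occlusion (efficacy) or to bleeding cessation
(safety) — against anticoagulant dose, with observation capped (60 min
for the rat models).  Times that reach the cap are censored, not exact.

The dose-response-time curve is modelled as a Hill saturation between
the saline baseline and the cap,

    RT(d) = baseline + (cap - baseline) / (1 + (rt50/d)^hill),

with multiplicative log-normal residuals.  Censored observations enter
the likelihood through the log-normal survival function rather than
being discarded or treated as exact.  RT50 is the dose at which the
fitted mean response time reaches (baseline + cap)/2, and the
therapeutic index is TI = RT50(bleeding) / RT50(occlusion).

Saline baselines measured in the source rat experiments are shipped as
defaults: 8.82 min for occlusion, 4.25 min for tail bleeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._base import FitResultsBase, summary_table

__all__ = [
    "SALINE_OCCLUSION_BASELINE_MIN",
    "SALINE_TAIL_BLEED_BASELINE_MIN",
    "RT50Model",
    "RT50Results",
    "TherapeuticIndexResult",
    "therapeutic_index",
    "SaphenousResult",
    "saphenous_metrics",
    "cross_model_correlation",
    "two_sample_ttest",
]

SALINE_OCCLUSION_BASELINE_MIN = 8.82
SALINE_TAIL_BLEED_BASELINE_MIN = 4.25


def hill_response_time(dose, rt50, hill, baseline, cap):
    """Saturating Hill curve for mean response time vs dose."""
    dose = np.asarray(dose, dtype=float)
    return baseline + (cap - baseline) / (1.0 + (rt50 / dose) ** hill)


class RT50Results(FitResultsBase):
    """Censored Hill fit: RT50 dose, Hill coefficient, residual scale."""

    def __init__(self, rt50_dose, rt50_se, hill, hill_se, sigma_log, baseline,
                 cap, dose_unit, loglik, n_obs, n_censored, converged):
        self.rt50_dose = rt50_dose
        self.rt50_se = rt50_se
        self.hill = hill
        self.hill_se = hill_se
        self.sigma_log = sigma_log
        self.baseline_min = baseline
        self.cap_min = cap
        self.dose_unit = dose_unit
        self.loglik = loglik
        self.n_obs = n_obs
        self.n_censored = n_censored
        self.converged = converged

    def predict(self, dose):
        return hill_response_time(dose, self.rt50_dose, self.hill,
                                  self.baseline_min, self.cap_min)

    def summary(self) -> str:
        rows = [
            (f"RT50 ({self.dose_unit})", self.rt50_dose, self.rt50_se),
            ("Hill coefficient", self.hill, self.hill_se),
            ("sigma (log-time)", self.sigma_log, np.nan),
        ]
        extra = [
            ("baseline (min)", f"{self.baseline_min:g}"),
            ("cap (min)", f"{self.cap_min:g}"),
            ("n / censored", f"{self.n_obs} / {self.n_censored}"),
            ("log-likelihood", f"{self.loglik:.3f}"),
            ("converged", str(self.converged)),
        ]
        return summary_table("Censored RT50 dose-response fit", rows, extra)


class RT50Model:
    """Censored-likelihood Hill fit of response time against dose.

    Parameters
    ----------
    dose, response_time_min, censored : arrays
        One record per animal.  ``censored=True`` means the observation
        hit the cap without the event occurring.
    cap_min : float
        Observation cap (60 min for the rat occlusion/tail models).
    baseline_min : float
        Saline-group mean response time; fixed, not estimated (the
        baseline is measured directly in the saline arm).
    dose_unit : str
        Carried through to TI computation for unit-mismatch checks.

    The likelihood treats log response time as Gaussian around the log
    of the Hill mean; censored records contribute the survival term
    P(T >= cap).  Optimisation is over (log rt50, log hill, log sigma),
    seeded by a least-squares fit to the uncensored records.
    """

    def __init__(self, dose, response_time_min, censored=None, *,
                 cap_min: float = 60.0,
                 baseline_min: float = SALINE_OCCLUSION_BASELINE_MIN,
                 dose_unit: str = "mg/kg"):
        self.dose = np.asarray(dose, dtype=float)
        self.rt = np.asarray(response_time_min, dtype=float)
        if censored is None:
            censored = self.rt >= cap_min
        self.censored = np.asarray(censored, dtype=bool)
        if not (self.dose.size == self.rt.size == self.censored.size):
            raise ValueError("dose, response time and censoring lengths differ")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive")
        if np.any(self.rt <= 0) or np.any(self.rt > cap_min + 1e-9):
            raise ValueError("response times must lie in (0, cap]")
        if cap_min <= baseline_min:
            raise ValueError("cap must exceed baseline")
        if np.unique(self.dose).size < 3:
            raise ValueError("need >= 3 dose levels")
        if np.all(self.censored):
            raise ValueError("no information below cap: all observations censored")
        self.cap = float(cap_min)
        self.baseline = float(baseline_min)
        self.dose_unit = dose_unit

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RT50Model":
        """Build from a records table with columns ``dose``,
        ``response_time_min`` and optional ``censored``/``cap_min``."""
        cens = df["censored"].to_numpy() if "censored" in df else None
        if "cap_min" in df and "cap_min" not in kwargs:
            caps = df["cap_min"].unique()
            if caps.size != 1:
                raise ValueError("records carry inconsistent caps")
            kwargs["cap_min"] = float(caps[0])
        if "dose_unit" in df and "dose_unit" not in kwargs:
            units = df["dose_unit"].unique()
            if units.size != 1:
                raise ValueError("records carry inconsistent dose units")
            kwargs["dose_unit"] = str(units[0])
        return cls(df["dose"].to_numpy(), df["response_time_min"].to_numpy(),
                   cens, **kwargs)

    # -- likelihood ---------------------------------------------------------

    def _negloglik(self, theta):
        rt50, hill, sigma = np.exp(theta)
        sigma = max(sigma, 1e-10)  # guard the noiseless limit
        mu = np.log(hill_response_time(self.dose, rt50, hill, self.baseline, self.cap))
        nll = 0.0
        unc = ~self.censored
        if np.any(unc):
            z = (np.log(self.rt[unc]) - mu[unc]) / sigma
            nll -= np.sum(stats.norm.logpdf(z) - np.log(sigma))
        if np.any(self.censored):
            zc = (np.log(self.cap) - mu[self.censored]) / sigma
            nll -= np.sum(stats.norm.logsf(zc))
        return nll

    def fit(self) -> RT50Results:
        unc = ~self.censored
        d_u, t_u = self.dose[unc], self.rt[unc]

        # stage 1: least squares on log times of uncensored records
        def resid(theta):
            rt50, hill = np.exp(theta)
            return np.log(hill_response_time(d_u, rt50, hill, self.baseline, self.cap)) - np.log(t_u)

        mid = 0.5 * (self.baseline + self.cap)
        above = t_u >= mid
        d0 = np.exp(np.interp(np.log(mid), np.log(np.sort(t_u)),
                              np.log(d_u[np.argsort(t_u)]))) if np.any(above) and np.any(~above) \
            else float(np.median(self.dose))
        start = np.log([max(d0, 1e-12), 1.5])
        ls = optimize.least_squares(resid, start, xtol=1e-15, ftol=1e-15, max_nfev=5000)
        sig0 = max(np.sqrt(2.0 * ls.cost / max(d_u.size, 1)), 1e-6)

        # stage 2: full censored MLE
        x0 = np.array([ls.x[0], ls.x[1], np.log(sig0)])
        sol = optimize.minimize(self._negloglik, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 4000})
        rt50, hill, sigma = np.exp(sol.x)

        # SEs from a numerical Hessian of the nll in log-parameter space
        se_rt50 = se_hill = np.nan
        if sigma > 1e-5:
            try:
                h = _numerical_hessian(self._negloglik, sol.x)
                cov = np.linalg.inv(h)
                se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
                se_rt50 = rt50 * se_log[0]
                se_hill = hill * se_log[1]
            except np.linalg.LinAlgError:
                pass

        return RT50Results(
            rt50_dose=float(rt50), rt50_se=float(se_rt50),
            hill=float(hill), hill_se=float(se_hill),
            sigma_log=float(sigma), baseline=self.baseline, cap=self.cap,
            dose_unit=self.dose_unit, loglik=float(-sol.fun),
            n_obs=int(self.dose.size), n_censored=int(self.censored.sum()),
            converged=bool(sol.success),
        )


def _numerical_hessian(f, x, eps=1e-5):
    n = x.size
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy(); xi[i] += eps; xi[j] += eps
            xj = x.copy(); xj[i] += eps
            xk = x.copy(); xk[j] += eps
            h[i, j] = h[j, i] = (f(xi) - f(xj) - f(xk) + f0) / eps**2
    return h


# ---------------------------------------------------------------------------
# therapeutic index and bleeding metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TherapeuticIndexResult:
    rt50_bleeding: float
    rt50_occlusion: float
    ti: float
    dose_unit: str

    def summary(self) -> str:
        rows = [("RT50 bleeding", self.rt50_bleeding, np.nan),
                ("RT50 occlusion", self.rt50_occlusion, np.nan),
                ("therapeutic index", self.ti, np.nan)]
        return summary_table("Therapeutic index", rows,
                             [("dose unit", self.dose_unit)])


def therapeutic_index(bleed: RT50Results, occl: RT50Results) -> TherapeuticIndexResult:
    """TI = RT50(bleeding) / RT50(occlusion); wider is safer.

    A wide TI means full antithrombotic efficacy is reached at doses far
    below those that abolish haemostasis.  Both fits must carry the same
    dose unit — mg/kg and U/kg doses are never auto-converted.
    """
    if bleed.dose_unit != occl.dose_unit:
        raise ValueError(
            f"dose unit mismatch: bleeding in {bleed.dose_unit!r}, "
            f"occlusion in {occl.dose_unit!r}")
    return TherapeuticIndexResult(
        rt50_bleeding=bleed.rt50_dose,
        rt50_occlusion=occl.rt50_dose,
        ti=bleed.rt50_dose / occl.rt50_dose,
        dose_unit=bleed.dose_unit,
    )


@dataclass(frozen=True)
class SaphenousResult:
    n_clots: int
    avg_bleed_time_min: float
    censored: bool  # True when no haemostasis occurred in the window


def saphenous_metrics(n_clots: int, window_min: float = 30.0) -> SaphenousResult:
    """Average bleeding time per event in the saphenous-vein model.

    The model repeatedly disrupts each clot; the average time per
    bleeding event is the observation window divided by the number of
    haemostatic events.  Zero clots means haemostasis never occurred:
    the bleeding time is censored at >= window.
    """
    if window_min <= 0:
        raise ValueError("window must be positive")
    if n_clots < 0:
        raise ValueError("clot count cannot be negative")
    if n_clots == 0:
        return SaphenousResult(0, float(window_min), censored=True)
    return SaphenousResult(int(n_clots), window_min / n_clots, censored=False)


# ---------------------------------------------------------------------------
# simple statistics
# ---------------------------------------------------------------------------

def cross_model_correlation(x, y) -> tuple[float, float]:
    """Pearson r with two-tailed p (t-transform) between paired group means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def two_sample_ttest(a, b, variant: str = "student") -> tuple[float, float]:
    """Two-tailed two-sample t test (Student pooled or Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)
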