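"""Biolayer interferometry 1:1 binding kinetics.

A BLI sensorgram records the optical-thickness response (nm) of a
ligand-coated biosensor through baseline, association and dissociation
phases.  Under the 1:1 Langmuir model with analyte concentration C,

    dR/dt = kon * C * (Rmax - R) - koff * R,

the association phase is mono-exponential,

    R(t) = Rmax * C / (C + KD) * (1 - exp(-(kon*C + koff) * t)),

and the dissociation phase decays as R_end * exp(-koff * t), with
KD = koff / kon.  The global fit shares (kon, koff, Rmax) across a
dilution series; the steady-state route fits the equilibrium isotherm
Req(C) = Rmax * C / (KD + C) instead, giving an independent KD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._base import FitResultsBase, summary_table

__all__ = [
    "Sensorgram",
    "simulate_1to1",
    "align_baseline",
    "extract_req",
    "ReqEstimate",
    "OneToOneModel",
    "OneToOneResults",
    "SteadyStateModel",
    "SteadyStateResults",
]


@dataclass
class Sensorgram:
    """One analyte concentration's BLI trace.

    ``phase`` labels each sample as ``baseline``, ``association`` or
    ``dissociation``; phase times are contiguous and association
    precedes dissociation.  ``conc_nM`` is the analyte concentration.
    """

    time_s: np.ndarray
    response_nm: np.ndarray
    phase: np.ndarray
    conc_nM: float
    ligand_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_nm = np.asarray(self.response_nm, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.time_s.size == self.response_nm.size == self.phase.size):
            raise ValueError("time, response and phase lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.conc_nM < 0:
            raise ValueError("analyte concentration must be non-negative")
        order = {"baseline": 0, "association": 1, "dissociation": 2}
        codes = [order[p] for p in self.phase]
        if np.any(np.diff(codes) < 0):
            raise ValueError("phases must appear in baseline/association/dissociation order")
        if 1 not in codes:
            raise ValueError("sensorgram lacks an association phase")

    def segment(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.phase == name
        return self.time_s[mask], self.response_nm[mask]


def _assoc_response(t, kon, koff, rmax, conc_M):
    kd = koff / kon
    kobs = kon * conc_M + koff
    return rmax * conc_M / (conc_M + kd) * (1.0 - np.exp(-kobs * t))


def simulate_1to1(
    kon: float,
    koff: float,
    rmax: float,
    conc_nM: float,
    t_assoc_s: float = 2400.0,
    t_dissoc_s: float = 3600.0,
    dt_s: float = 1.0,
    t_baseline_s: float = 0.0,
    ligand_id: str = "",
) -> Sensorgram:
    """Noise-free 1:1 Langmuir sensorgram (closed form).

    kon in M^-1 s^-1, koff in s^-1, rmax in nm, conc in nM.  The
    dissociation phase starts from the association end-point.
    """
    if kon <= 0 or koff <= 0 or rmax <= 0:
        raise ValueError("kon, koff and Rmax must be positive")
    if conc_nM < 0:
        raise ValueError("analyte concentration must be non-negative")
    if t_assoc_s <= 0 or t_dissoc_s < 0 or dt_s <= 0:
        raise ValueError("phase durations and dt must be positive")
    conc_M = conc_nM * 1e-9

    segs_t, segs_r, segs_p = [], [], []
    t0 = 0.0
    if t_baseline_s > 0:
        tb = np.arange(0.0, t_baseline_s, dt_s)
        segs_t.append(tb)
        segs_r.append(np.zeros_like(tb))
        segs_p.append(np.full(tb.size, "baseline", dtype=object))
        t0 = t_baseline_s
    ta = np.arange(0.0, t_assoc_s + 0.5 * dt_s, dt_s)
    ra = _assoc_response(ta, kon, koff, rmax, conc_M)
    segs_t.append(t0 + ta)
    segs_r.append(ra)
    segs_p.append(np.full(ta.size, "association", dtype=object))
    if t_dissoc_s > 0:
        td = np.arange(dt_s, t_dissoc_s + 0.5 * dt_s, dt_s)
        rd = ra[-1] * np.exp(-koff * td)
        segs_t.append(t0 + t_assoc_s + td)
        segs_r.append(rd)
        segs_p.append(np.full(td.size, "dissociation", dtype=object))
    return Sensorgram(
        time_s=np.concatenate(segs_t),
        response_nm=np.concatenate(segs_r),
        phase=np.concatenate(segs_p),
        conc_nM=conc_nM,
        ligand_id=ligand_id,
    )


def align_baseline(sg: Sensorgram, window_s: float = 30.0) -> Sensorgram:
    """Zero a trace to the mean of the final ``window_s`` of its baseline.

    Mirrors the reference-well subtraction step: responses are shifted
    so the pre-association signal averages zero.  A trace without a
    baseline phase is returned unchanged.
    """
    tb, rb = sg.segment("baseline")
    if tb.size == 0:
        return sg
    tail = tb >= tb[-1] - window_s
    offset = float(rb[tail].mean())
    return Sensorgram(sg.time_s, sg.response_nm - offset, sg.phase,
                      sg.conc_nM, sg.ligand_id)


# ---------------------------------------------------------------------------
# Req extraction and steady-state isotherm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReqEstimate:
    req_nm: float
    se_nm: float
    kobs: float
    reliable: bool


def extract_req(sg: Sensorgram, se_fraction_limit: float = 0.5) -> ReqEstimate:
    """Equilibrium response from the association phase.

    Fits R(t) = Req * (1 - exp(-kobs * t)) to the association segment;
    Req is the fitted plateau, not the last sample, so traces that have
    not fully saturated are extrapolated correctly.  A plateau whose
    standard error exceeds ``se_fraction_limit`` of its value (a
    far-from-equilibrium, near-linear trace) is flagged unreliable.
    """
    ta, ra = sg.segment("association")
    if ta.size < 5:
        raise ValueError("association phase too short")
    t = ta - ta[0]
    span = float(ra[-1] - ra[0])
    if span <= 0:
        raise ValueError("association response does not increase")

    def resid(theta):
        log_req, log_kobs = theta
        return np.exp(log_req) * (1.0 - np.exp(-np.exp(log_kobs) * t)) - ra

    x0 = [np.log(max(span, 1e-12)), np.log(2.0 / max(t[-1], 1e-9))]
    sol = optimize.least_squares(resid, x0, xtol=1e-15, ftol=1e-15, max_nfev=10000)
    req = float(np.exp(sol.x[0]))
    kobs = float(np.exp(sol.x[1]))
    dof = max(t.size - 2, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se = req * np.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        se = np.nan
    reliable = np.isfinite(se) and se <= se_fraction_limit * req and kobs * t[-1] >= 1.0
    return ReqEstimate(req_nm=req, se_nm=float(se), kobs=kobs, reliable=bool(reliable))


class SteadyStateResults(FitResultsBase):
    def __init__(self, kd_nM, kd_se_nM, rmax, rmax_se, rss, nobs, saturated):
        self.KD_eq_nM = kd_nM
        self.KD_eq_se_nM = kd_se_nM
        self.Rmax_nm = rmax
        self.Rmax_se_nm = rmax_se
        self.rss = rss
        self.nobs = nobs
        self.saturated_design = saturated

    def predict(self, conc_nM):
        c = np.asarray(conc_nM, dtype=float)
        return self.Rmax_nm * c / (self.KD_eq_nM + c)

    def summary(self) -> str:
        rows = [("KD_eq (nM)", self.KD_eq_nM, self.KD_eq_se_nM),
                ("Rmax (nm)", self.Rmax_nm, self.Rmax_se_nm)]
        extra = [("RSS", f"{self.rss:.3e}"), ("n", f"{self.nobs}"),
                 ("saturated design", str(self.saturated_design))]
        return summary_table("Steady-state affinity isotherm", rows, extra)


class SteadyStateModel:
    """Least-squares fit of the equilibrium isotherm Req = Rmax*C/(KD+C)."""

    def __init__(self, conc_nM, req_nm):
        self.conc = np.asarray(conc_nM, dtype=float)
        self.req = np.asarray(req_nm, dtype=float)
        if self.conc.size != self.req.size:
            raise ValueError("conc and Req lengths differ")
        if np.unique(self.conc).size < 3:
            raise ValueError("need >= 3 concentrations")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")

    def fit(self) -> SteadyStateResults:
        c, r = self.conc, self.req
        spread = (r.max() - r.min()) / max(r.max(), 1e-300)
        saturated = spread < 0.05  # Req flat across the dilution series

        def resid(theta):
            log_kd, log_rmax = theta
            kd, rmax = np.exp(log_kd), np.exp(log_rmax)
            return rmax * c / (kd + c) - r

        # half-max initialisation
        half = 0.5 * r.max()
        kd0 = float(np.interp(half, np.sort(r), c[np.argsort(r)]))
        x0 = [np.log(max(kd0, 1e-6)), np.log(max(r.max(), 1e-12))]
        sol = optimize.least_squares(resid, x0, xtol=1e-15, ftol=1e-15, max_nfev=10000)
        if not sol.success:
            raise RuntimeError(f"steady-state fit did not converge: {sol.message}")
        kd, rmax = np.exp(sol.x)
        dof = max(c.size - 2, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
            se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
            kd_se, rmax_se = kd * se_log[0], rmax * se_log[1]
        except np.linalg.LinAlgError:
            kd_se = rmax_se = np.nan
        return SteadyStateResults(float(kd), float(kd_se), float(rmax),
                                  float(rmax_se), float(2.0 * sol.cost),
                                  int(c.size), bool(saturated))


# ---------------------------------------------------------------------------
# global kinetic fit
# ---------------------------------------------------------------------------

class OneToOneResults(FitResultsBase):
    """Global 1:1 kinetic fit: kon, koff, KD = koff/kon, Rmax."""

    def __init__(self, kon, kon_se, koff, koff_se, rmax, rmax_se, rss, nobs,
                 mode, concentrations, ill_conditioned):
        self.kon = kon
        self.kon_se = kon_se
        self.koff = koff
        self.koff_se = koff_se
        self.Rmax_nm = rmax
        self.Rmax_se_nm = rmax_se
        self.rss = rss
        self.nobs = nobs
        self.mode = mode
        self.concentrations_nM = concentrations
        self.ill_conditioned = ill_conditioned

    @property
    def KD_kinetic_nM(self) -> float:
        return self.koff / self.kon * 1e9

    @property
    def dissociation_half_life_s(self) -> float:
        return float(np.log(2.0) / self.koff)

    def predict(self, sg: Sensorgram) -> np.ndarray:
        return _predict_trace(sg, self.kon, self.koff, self.Rmax_nm)

    def summary(self) -> str:
        rows = [("kon (1/M/s)", self.kon, self.kon_se),
                ("koff (1/s)", self.koff, self.koff_se),
                ("Rmax (nm)", self.Rmax_nm, self.Rmax_se_nm),
                ("KD kinetic (nM)", self.KD_kinetic_nM, np.nan)]
        extra = [("mode", self.mode),
                 ("t1/2 dissociation (s)", f"{self.dissociation_half_life_s:.1f}"),
                 ("RSS", f"{self.rss:.3e}"), ("n samples", f"{self.nobs}"),
                 ("ill-conditioned design", str(self.ill_conditioned))]
        return summary_table("BLI 1:1 kinetic fit", rows, extra)


def _predict_trace(sg: Sensorgram, kon, koff, rmax) -> np.ndarray:
    conc_M = sg.conc_nM * 1e-9
    out = np.zeros_like(sg.time_s)
    ta, _ = sg.segment("association")
    td, _ = sg.segment("dissociation")
    am = sg.phase == "association"
    dm = sg.phase == "dissociation"
    t0a = ta[0] if ta.size else 0.0
    ra = _assoc_response(sg.time_s[am] - t0a, kon, koff, rmax, conc_M)
    out[am] = ra
    if td.size:
        r_end = _assoc_response(ta[-1] - t0a, kon, koff, rmax, conc_M)
        out[dm] = r_end * np.exp(-koff * (sg.time_s[dm] - ta[-1]))
    return out


class OneToOneModel:
    """Global nonlinear fit of the 1:1 model across a dilution series.

    ``mode="global"`` (the vendor-standard choice for a multi-point
    series) shares kon, koff and Rmax across all concentrations;
    ``mode="per_curve"`` fits each trace separately for diagnostics and
    returns the concentration-weighted consensus.  The design is
    flagged ill-conditioned when all analyte concentrations sit far
    (>= 100x) to one side of the fitted KD.
    """

    def __init__(self, sensorgrams, mode: str = "global"):
        if mode not in ("global", "per_curve"):
            raise ValueError("mode must be 'global' or 'per_curve'")
        sensorgrams = list(sensorgrams)
        if not sensorgrams:
            raise ValueError("no sensorgrams supplied")
        if mode == "global" and len({sg.conc_nM for sg in sensorgrams}) < 3:
            raise ValueError("global fit needs >= 3 analyte concentrations")
        self.sensorgrams = [align_baseline(sg) for sg in sensorgrams]
        self.mode = mode

    def _residuals(self, theta, sgs):
        kon, koff, rmax = 10.0 ** theta
        res = [ _predict_trace(sg, kon, koff, rmax) - sg.response_nm for sg in sgs ]
        return np.concatenate(res)

    def _fit_group(self, sgs):
        # initial guesses: koff from the dissociation tail, kon via an
        # assumed mid-nanomolar KD, Rmax from the largest response
        rmax0 = max(max(sg.response_nm.max() for sg in sgs), 1e-6)
        koff0 = 1e-3
        for sg in sgs:
            td, rd = sg.segment("dissociation")
            if td.size >= 5 and rd[0] > 0 and rd[-1] > 0 and rd[-1] < rd[0]:
                koff0 = max(np.log(rd[0] / rd[-1]) / (td[-1] - td[0]), 1e-7)
                break
        conc_mid = np.median([sg.conc_nM for sg in sgs if sg.conc_nM > 0]) * 1e-9
        kon0 = koff0 / max(conc_mid, 1e-12)
        best = None
        for scale in (1.0, 10.0, 0.1):
            x0 = np.log10([kon0 * scale, koff0, rmax0 * 1.2])
            sol = optimize.least_squares(self._residuals, x0, args=(sgs,),
                                         xtol=1e-15, ftol=1e-15, max_nfev=20000)
            if best is None or sol.cost < best.cost - 1e-18:
                best = sol
        return best

    def fit(self) -> OneToOneResults:
        sgs = [sg for sg in self.sensorgrams if sg.conc_nM > 0]
        if not sgs:
            raise ValueError("all sensorgrams have zero analyte concentration")
        if self.mode == "global":
            sol = self._fit_group(sgs)
        else:
            sols = [self._fit_group([sg]) for sg in sgs]
            costs = np.array([s.cost for s in sols])
            sol = sols[int(np.argmin(costs))]
        if not sol.success:
            raise RuntimeError(f"1:1 kinetic fit did not converge: {sol.message}")
        kon, koff, rmax = 10.0 ** sol.x
        nobs = sum(sg.time_s.size for sg in sgs)
        dof = max(nobs - 3, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
            se_log = np.sqrt(np.maximum(np.diag(cov), 0.0)) * np.log(10.0)
            kon_se, koff_se, rmax_se = kon * se_log[0], koff * se_log[1], rmax * se_log[2]
        except np.linalg.LinAlgError:
            kon_se = koff_se = rmax_se = np.nan
        kd_nM = koff / kon * 1e9
        concs = sorted(sg.conc_nM for sg in sgs)
        ill = (max(concs) < kd_nM / 100.0) or (min(concs) > kd_nM * 100.0)
        return OneToOneResults(
            kon=float(kon), kon_se=float(kon_se),
            koff=float(koff), koff_se=float(koff_se),
            rmax=float(rmax), rmax_se=float(rmax_se),
            rss=float(2.0 * sol.cost), nobs=int(nobs), mode=self.mode,
            concentrations=concs, ill_conditioned=bool(ill),
        )
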