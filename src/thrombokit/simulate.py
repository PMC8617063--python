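"""Synthetic assay data with known ground truth.

No raw data accompany the source study (the measurements are animal and
donor-plasma assays), so every read-out the analysis chain consumes can
be generated here with stated truth parameters, explicit noise models
and reproducible seeds:

* linear (fast-binding) progress curves whose slopes follow the
  Morrison fractional velocity,
* tight-binding inhibition series (fractional velocity vs inhibitor),
* sigmoidal clot-waveform transmittance traces,
* single-pulse thrombograms with lag/peak/area structure,
* cap-censored in-vivo dose-response-time records with multiplicative
  log-normal noise,
* two-phase 1:1 Langmuir BLI sensorgrams.

Noise is additive Gaussian for optical traces and multiplicative
log-normal for response times (times are positive by construction).
Zero-noise output is exactly the forward model of the consuming module
— the generators call the same functions the fitters use.  Each
generator returns its data together with a ``truth`` sidecar mapping for
parameter-recovery tests.  One integer seed drives each spec;
per-replicate sub-streams are derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .bli import Sensorgram, simulate_1to1
from .invivo import hill_response_time
from .kinetics import InhibitionSeries, ProgressCurve, morrison_velocity

__all__ = [
    "SimSpec",
    "gen_progress_curves",
    "gen_inhibition_series",
    "gen_cwa_trace",
    "gen_thrombogram",
    "gen_invivo_doseresponse",
    "gen_sensorgrams",
    "generate",
]

_ASSAY_KINDS = (
    "progress_curve",
    "inhibition_panel",
    "cwa_trace",
    "thrombogram",
    "invivo_doseresponse",
    "sensorgram",
)


@dataclass
class SimSpec:
    """Specification of one synthetic assay run.

    ``truth`` maps model-parameter names to values in the consuming
    module's units; ``noise_sd`` is the additive Gaussian SD in the
    read-out's native unit (for in-vivo records it is the log-normal
    sigma on the log-time scale).  A fixed seed yields byte-identical
    output.
    """

    assay_kind: str
    truth: dict[str, Any]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay_kind not in _ASSAY_KINDS:
            raise ValueError(f"unknown assay kind {self.assay_kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rng_streams(self, n: int) -> list[np.random.Generator]:
        """Deterministic per-replicate generators derived from the seed."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def _require(truth: dict, *keys: str) -> None:
    missing = [k for k in keys if k not in truth]
    if missing:
        raise ValueError(f"truth is missing parameters: {missing}")


# ---------------------------------------------------------------------------
# enzyme kinetics
# ---------------------------------------------------------------------------

def _ki_prime_nM(truth: dict, S_uM: float) -> float:
    """Apparent Ki' in nM from either a direct value or (Ki, Km, S)."""
    if "Ki_prime_pM" in truth:
        return truth["Ki_prime_pM"] / 1e3
    _require(truth, "Ki_pM", "Km_uM")
    return truth["Ki_pM"] / 1e3 * (1.0 + S_uM / truth["Km_uM"])


def gen_progress_curves(spec: SimSpec) -> tuple[list[ProgressCurve], dict]:
    """Linear progress curves under Morrison fractional velocities.

    truth: ``v0_au_per_min``, ``Et_nM``, ``It_nM`` (list), ``S_uM``,
    ``duration_s``, ``dt_s``, and either ``Ki_prime_pM`` or
    (``Ki_pM``, ``Km_uM``) for competitive mode.  Optional ``A0_au``
    sets the starting absorbance (default 0.05).
    """
    t = spec.truth
    _require(t, "v0_au_per_min", "Et_nM", "It_nM", "S_uM", "duration_s", "dt_s")
    if t["dt_s"] <= 0:
        raise ValueError("dt must be positive")
    it_list = np.asarray(t["It_nM"], dtype=float)
    if np.any(it_list < 0) or t["Et_nM"] <= 0 or t["S_uM"] <= 0:
        raise ValueError("concentrations must be non-negative (Et, S positive)")
    ki_nM = _ki_prime_nM(t, t["S_uM"])
    time_s = np.arange(0.0, t["duration_s"] + 0.5 * t["dt_s"], t["dt_s"])
    a0 = t.get("A0_au", 0.05)
    streams = spec.rng_streams(it_list.size)
    curves = []
    for it, rng in zip(it_list, streams):
        fv = morrison_velocity(ki_nM, it, t["Et_nM"], 1.0)
        slope = t["v0_au_per_min"] * fv  # AU/min
        absorbance = a0 + slope * time_s / 60.0
        if spec.noise_sd > 0:
            absorbance = absorbance + rng.normal(0.0, spec.noise_sd, time_s.size)
        curves.append(ProgressCurve(
            time_s=time_s.copy(), absorbance_au=absorbance,
            Et_nM=t["Et_nM"], It_nM=float(it), S_uM=t["S_uM"],
            inhibitor_id=t.get("inhibitor_id", "synthetic"),
            protease_id=t.get("protease_id", "thrombin"),
        ))
    truth = dict(t, Ki_prime_pM_effective=ki_nM * 1e3)
    return curves, truth


def gen_inhibition_series(spec: SimSpec) -> tuple[InhibitionSeries, dict]:
    """Fractional-velocity points vs/vo with Gaussian noise on vs/vo.

    truth: ``Et_nM``, ``S_uM``, ``It_nM`` list, and ``Ki_prime_pM`` or
    (``Ki_pM``, ``Km_uM``).  ``noise_sd`` is the SD on the fractional
    velocity (0.02 models ~2% velocity noise).
    """
    t = spec.truth
    _require(t, "Et_nM", "S_uM", "It_nM")
    it = np.asarray(t["It_nM"], dtype=float)
    ki_nM = _ki_prime_nM(t, t["S_uM"])
    fv = morrison_velocity(ki_nM, it, t["Et_nM"], 1.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        fv = np.clip(fv + rng.normal(0.0, spec.noise_sd, it.size), 0.0, None)
        fv[it == 0] = 1.0  # the reference defines the scale
    series = InhibitionSeries(Et_nM=t["Et_nM"], S_uM=t["S_uM"], It_nM=it,
                              fractional_velocity=fv,
                              inhibitor_id=t.get("inhibitor_id", "synthetic"))
    return series, dict(t, Ki_prime_pM_effective=ki_nM * 1e3)


# ---------------------------------------------------------------------------
# plasma traces
# ---------------------------------------------------------------------------

def gen_cwa_trace(spec: SimSpec) -> tuple[pd.DataFrame, dict]:
    """Monotone-decreasing logistic transmittance trace.

    truth: ``baseline_pct``, ``drop_pct``, ``midpoint_s``, ``scale_s``
    (logistic time constant), ``duration_s``, ``dt_s``.  The noiseless
    minimum slope is -drop/(4*scale) at the midpoint.
    """
    t = spec.truth
    _require(t, "baseline_pct", "drop_pct", "midpoint_s", "scale_s",
             "duration_s", "dt_s")
    if t["drop_pct"] > t["baseline_pct"]:
        raise ValueError("drop cannot exceed baseline")
    if t["drop_pct"] < 0 or t["scale_s"] <= 0 or t["dt_s"] <= 0:
        raise ValueError("drop must be >= 0; scale and dt positive")
    time_s = np.arange(0.0, t["duration_s"] + 0.5 * t["dt_s"], t["dt_s"])
    tr = t["baseline_pct"] - t["drop_pct"] * expit((time_s - t["midpoint_s"]) / t["scale_s"])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        tr = tr + rng.normal(0.0, spec.noise_sd, time_s.size)
    df = pd.DataFrame({"time_s": time_s, "transmittance_pct": tr})
    truth = dict(t, min1_true=-t["drop_pct"] / (4.0 * t["scale_s"]),
                 clot_time_true_s=t["midpoint_s"])
    return df, truth


def _gamma_pulse(time_min, lt, tt_peak, peak, shape):
    """Gamma-density pulse: zero before LT, maximum ``peak`` at TTpeak."""
    theta = (tt_peak - lt) / (shape - 1.0)
    dist = stats.gamma(a=shape, scale=theta)
    x = np.asarray(time_min, dtype=float) - lt
    y = np.where(x > 0, dist.pdf(np.clip(x, 0, None)), 0.0)
    fmax = dist.pdf(tt_peak - lt)
    return peak * y / fmax, dist, fmax


def gen_thrombogram(spec: SimSpec) -> tuple[pd.DataFrame, dict]:
    """Single-pulse thrombogram: gamma-shaped, shifted by the lag time.

    truth: ``LT_min``, ``TTpeak_min``, ``peak_nM``, ``shape`` (gamma
    shape > 1, controls decay), ``duration_min``, ``dt_min``.  The
    sidecar reports the analytic ETP of the continuous pulse truncated
    at the trace duration.
    """
    t = spec.truth
    _require(t, "LT_min", "TTpeak_min", "peak_nM", "duration_min", "dt_min")
    if t["TTpeak_min"] <= t["LT_min"]:
        raise ValueError("TTpeak must exceed LT")
    if t["peak_nM"] <= 0:
        raise ValueError("peak must be positive")
    shape = t.get("shape", 3.0)
    if shape <= 1.0:
        raise ValueError("gamma shape must exceed 1 (mode must be interior)")
    time_min = np.arange(0.0, t["duration_min"] + 0.5 * t["dt_min"], t["dt_min"])
    y, dist, fmax = _gamma_pulse(time_min, t["LT_min"], t["TTpeak_min"],
                                 t["peak_nM"], shape)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = np.clip(y + rng.normal(0.0, spec.noise_sd, y.size), 0.0, None)
    df = pd.DataFrame({"time_min": time_min, "thrombin_nM": y})
    etp_true = t["peak_nM"] / fmax * dist.cdf(t["duration_min"] - t["LT_min"])
    truth = dict(t, shape=shape, ETP_true_nM_min=float(etp_true))
    return df, truth


# ---------------------------------------------------------------------------
# in-vivo dose-response
# ---------------------------------------------------------------------------

def gen_invivo_doseresponse(spec: SimSpec) -> tuple[pd.DataFrame, dict]:
    """Cap-censored response-time records from a Hill latent curve.

    truth: ``baseline_min``, ``cap_min``, ``rt50``, ``hill``, ``doses``
    (list), ``n_per_dose`` (int or list), optional ``dose_unit`` and
    ``model``.  ``noise_sd`` is the log-normal sigma on log time
    (0.2 models 20% noise); latent times at or above the cap are
    recorded as the cap with ``censored=True``.
    """
    t = spec.truth
    _require(t, "baseline_min", "cap_min", "rt50", "hill", "doses", "n_per_dose")
    if t["cap_min"] <= t["baseline_min"]:
        raise ValueError("cap must exceed baseline")
    doses = np.asarray(t["doses"], dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    n_per = t["n_per_dose"]
    n_list = [int(n_per)] * doses.size if np.isscalar(n_per) else [int(n) for n in n_per]
    if len(n_list) != doses.size:
        raise ValueError("n_per_dose list must match dose list")
    streams = spec.rng_streams(doses.size)
    rows = []
    sid = 0
    for d, n, rng in zip(doses, n_list, streams):
        latent = hill_response_time(d, t["rt50"], t["hill"],
                                    t["baseline_min"], t["cap_min"])
        times = latent * np.exp(rng.normal(0.0, spec.noise_sd, n)) \
            if spec.noise_sd > 0 else np.full(n, latent)
        for x in times:
            cens = x >= t["cap_min"]
            rows.append({
                "subject_id": f"r{sid:04d}",
                "model": t.get("model", "occlusion"),
                "dose": d,
                "dose_unit": t.get("dose_unit", "mg/kg"),
                "response_time_min": t["cap_min"] if cens else float(x),
                "censored": bool(cens),
                "cap_min": t["cap_min"],
            })
            sid += 1
    return pd.DataFrame(rows), dict(t)


# ---------------------------------------------------------------------------
# BLI
# ---------------------------------------------------------------------------

def gen_sensorgrams(spec: SimSpec) -> tuple[list[Sensorgram], dict]:
    """1:1 Langmuir sensorgrams across an analyte dilution series.

    truth: ``kon`` (1/M/s), ``koff`` (1/s), ``Rmax_nm``, ``conc_nM``
    (list), ``t_assoc_s``, ``t_dissoc_s``, optional ``dt_s`` and
    ``t_baseline_s``.
    """
    t = spec.truth
    _require(t, "kon", "koff", "Rmax_nm", "conc_nM", "t_assoc_s", "t_dissoc_s")
    if t["kon"] <= 0 or t["koff"] <= 0 or t["Rmax_nm"] <= 0:
        raise ValueError("kon, koff and Rmax must be positive")
    concs = np.asarray(t["conc_nM"], dtype=float)
    streams = spec.rng_streams(concs.size)
    out = []
    for c, rng in zip(concs, streams):
        sg = simulate_1to1(t["kon"], t["koff"], t["Rmax_nm"], float(c),
                           t["t_assoc_s"], t["t_dissoc_s"],
                           dt_s=t.get("dt_s", 1.0),
                           t_baseline_s=t.get("t_baseline_s", 0.0),
                           ligand_id=t.get("ligand_id", "synthetic"))
        if spec.noise_sd > 0:
            sg = Sensorgram(sg.time_s,
                            sg.response_nm + rng.normal(0.0, spec.noise_sd, sg.time_s.size),
                            sg.phase, sg.conc_nM, sg.ligand_id)
        out.append(sg)
    truth = dict(t, KD_nM=t["koff"] / t["kon"] * 1e9)
    return out, truth


_DISPATCH = {
    "progress_curve": gen_progress_curves,
    "inhibition_panel": gen_inhibition_series,
    "cwa_trace": gen_cwa_trace,
    "thrombogram": gen_thrombogram,
    "invivo_doseresponse": gen_invivo_doseresponse,
    "sensorgram": gen_sensorgrams,
}


def generate(spec: SimSpec):
    """Dispatch a SimSpec to its generator; returns (data, truth)."""
    return _DISPATCH[spec.assay_kind](spec)
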