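"""Unit conversions and CSV table I/O with schema validation.

Covers the measurement-side plumbing of the assay chain:

* UFH activity-to-molar conversion (heparin is dosed in activity
  units; comparison with molecularly defined inhibitors on one axis
  needs its specific activity and average molecular weight),
* peptide concentration from UV absorbance at 280 nm via
  Gill-von Hippel extinction coefficients (with an A205 standard-curve
  fallback for Tyr/Trp-free peptides),
* long-format CSV readers/writers for every trace and record table the
  fit modules consume, validated against fixed schemas.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bli import Sensorgram
from .kinetics import ProgressCurve

__all__ = [
    "UnitContext",
    "ufh_units_to_molar",
    "extinction_coefficient_280",
    "conc_from_absorbance",
    "StandardCurve",
    "SchemaError",
    "load_inhibitor_table",
    "read_progress_curves",
    "write_progress_curves",
    "read_trace",
    "read_invivo_records",
    "write_invivo_records",
    "read_sensorgrams",
    "write_sensorgrams",
]


@dataclass(frozen=True)
class UnitContext:
    """Constants for unit conversions.

    ``ufh_specific_activity`` (U/mg) and ``ufh_mw`` (g/mol) are the
    measured/literature values shipped as defaults; ``path_length`` is
    the cuvette path in cm for Beer-Lambert conversions.
    """

    ufh_specific_activity_u_per_mg: float = 183.5
    ufh_mw_g_per_mol: float = 10900.0
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ufh_specific_activity_u_per_mg, self.ufh_mw_g_per_mol,
               self.path_length_cm) <= 0:
            raise ValueError("unit-context constants must be positive")


DEFAULT_UNITS = UnitContext()


def ufh_units_to_molar(u_per_ml: float, ctx: UnitContext = DEFAULT_UNITS) -> float:
    """Convert UFH activity (U/ml) to micromolar.

    U/ml -> mg/ml via the specific activity, then -> mol/l via the
    average molecular weight.  With the default constants 1 U/ml is
    about 0.50 uM.
    """
    if u_per_ml < 0:
        raise ValueError("activity concentration cannot be negative")
    mg_per_ml = u_per_ml / ctx.ufh_specific_activity_u_per_mg
    mol_per_l = mg_per_ml / ctx.ufh_mw_g_per_mol  # (g/l) / (g/mol)
    return mol_per_l * 1e6


# Gill & von Hippel molar extinction coefficients at 280 nm (M^-1 cm^-1)
_EPS_TYR = 1490.0
_EPS_TRP = 5500.0
_EPS_CYSTINE = 125.0
_AA = set("ACDEFGHIKLMNPQRSTVWY")


def extinction_coefficient_280(sequence: str) -> float:
    """Molar extinction coefficient at 280 nm from a peptide sequence.

    eps280 = 1490*nTyr + 5500*nTrp + 125*nCystine, counting cystines as
    Cys pairs.  A zero coefficient (no Tyr/Trp) signals that the A280
    route is unusable and concentration must come from an A205 standard
    curve instead.
    """
    seq = sequence.strip().upper()
    bad = sorted(set(seq) - _AA)
    if bad:
        raise ValueError(f"unknown residue codes: {bad}")
    return (_EPS_TYR * seq.count("Y") + _EPS_TRP * seq.count("W")
            + _EPS_CYSTINE * (seq.count("C") // 2))


def conc_from_absorbance(a: float, epsilon: float,
                         ctx: UnitContext = DEFAULT_UNITS) -> float:
    """Beer-Lambert concentration (mol/l) from absorbance.

    Raises for epsilon = 0 with a pointer to the standard-curve mode.
    """
    if epsilon < 0:
        raise ValueError("extinction coefficient cannot be negative")
    if epsilon == 0:
        raise ValueError(
            "extinction coefficient is zero (no Tyr/Trp): use an A205 "
            "StandardCurve instead")
    return a / (epsilon * ctx.path_length_cm)


class StandardCurve:
    """Linear absorbance-to-concentration map from reference pairs.

    Fits A = slope*conc + intercept by OLS on peptides of known
    concentration, then inverts it for unknowns — the A205 fallback for
    peptides without aromatic residues.
    """

    def __init__(self, known_conc, absorbance):
        c = np.asarray(known_conc, dtype=float)
        a = np.asarray(absorbance, dtype=float)
        if c.size != a.size or c.size < 2:
            raise ValueError("need >= 2 reference pairs")
        self.slope, self.intercept = np.polyfit(c, a, 1)
        if self.slope <= 0:
            raise ValueError("standard curve must have positive slope")

    def concentration(self, a: float) -> float:
        return (a - self.intercept) / self.slope


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """A CSV table failed schema validation."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; "
                          f"found {list(df.columns)}")


def load_inhibitor_table() -> pd.DataFrame:
    """The bundled thrombin-inhibitor Ki table.

    Columns: peptide_id, sequence, Ki_pM, Ki_SE_pM, note.  Peptides
    without measurable inhibition (activation instead) carry NaN Ki and
    an explanatory note.
    """
    ref = importlib.resources.files("thrombokit") / "data" / "thrombin_inhibitor_ki.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


PROGRESS_COLUMNS = ["time_s", "absorbance_au", "Et_nM", "It_nM", "S_uM",
                    "inhibitor_id", "protease_id"]


def read_progress_curves(path) -> list[ProgressCurve]:
    """Read long-format progress curves (one row per sample).

    Curves are keyed by (inhibitor_id, protease_id, Et_nM, It_nM, S_uM).
    """
    df = pd.read_csv(path)
    _check_columns(df, PROGRESS_COLUMNS, path)
    curves = []
    keys = ["inhibitor_id", "protease_id", "Et_nM", "It_nM", "S_uM"]
    for (inh, prot, et, it, s), g in df.groupby(keys, sort=True, dropna=False):
        g = g.sort_values("time_s")
        curves.append(ProgressCurve(
            time_s=g["time_s"].to_numpy(),
            absorbance_au=g["absorbance_au"].to_numpy(),
            Et_nM=float(et), It_nM=float(it), S_uM=float(s),
            inhibitor_id=str(inh), protease_id=str(prot)))
    return curves


def write_progress_curves(curves, path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "time_s": c.time_s, "absorbance_au": c.absorbance_au,
            "Et_nM": c.Et_nM, "It_nM": c.It_nM, "S_uM": c.S_uM,
            "inhibitor_id": c.inhibitor_id, "protease_id": c.protease_id}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace(path, time_col: str, signal_col: str) -> pd.DataFrame:
    """Read a generic time/signal trace table (CWA or thrombogram)."""
    df = pd.read_csv(path)
    _check_columns(df, [time_col, signal_col], path)
    if df[time_col].isna().any() or df[signal_col].isna().any():
        bad = int(df[[time_col, signal_col]].isna().any(axis=1).idxmax())
        raise SchemaError(f"{path}: missing value near row {bad}")
    return df.sort_values(time_col).reset_index(drop=True)


INVIVO_COLUMNS = ["subject_id", "model", "dose", "dose_unit",
                  "response_time_min", "censored", "cap_min"]


def read_invivo_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, INVIVO_COLUMNS, path)
    df["censored"] = df["censored"].astype(bool)
    bad = df.index[(df["response_time_min"] <= 0)
                   | (df["response_time_min"] > df["cap_min"] + 1e-9)]
    if len(bad):
        raise SchemaError(f"{path}: response_time_min outside (0, cap] at rows "
                          f"{list(bad[:5])}")
    viol = df.index[df["censored"]
                    & (df["response_time_min"] != df["cap_min"])]
    if len(viol):
        raise SchemaError(f"{path}: censored rows must sit at the cap, rows "
                          f"{list(viol[:5])}")
    return df


def write_invivo_records(df: pd.DataFrame, path) -> None:
    _check_columns(df, INVIVO_COLUMNS, path)
    df.to_csv(path, index=False)


SENSORGRAM_COLUMNS = ["time_s", "response_nm", "phase", "conc_nM", "ligand_id"]


def read_sensorgrams(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    _check_columns(df, SENSORGRAM_COLUMNS, path)
    allowed = {"baseline", "association", "dissociation"}
    bad = set(df["phase"].unique()) - allowed
    if bad:
        raise SchemaError(f"{path}: unknown phase labels {sorted(bad)}")
    out = []
    for (conc, lig), g in df.groupby(["conc_nM", "ligand_id"], sort=True):
        g = g.sort_values("time_s")
        out.append(Sensorgram(
            time_s=g["time_s"].to_numpy(),
            response_nm=g["response_nm"].to_numpy(),
            phase=g["phase"].to_numpy(dtype=object),
            conc_nM=float(conc), ligand_id=str(lig)))
    return out


def write_sensorgrams(sensorgrams, path) -> None:
    frames = []
    for sg in sensorgrams:
        frames.append(pd.DataFrame({
            "time_s": sg.time_s, "response_nm": sg.response_nm,
            "phase": sg.phase, "conc_nM": sg.conc_nM,
            "ligand_id": sg.ligand_id}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
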