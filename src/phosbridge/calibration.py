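"""TW-IMS CCS calibration, random-coil trendline, and conformer readout.

Traveling-wave ion mobility drift times have no closed-form relation to
collision cross section; they are calibrated against ions of known CCS.
The standard protocol is used here:

1. correct each drift time for mass-dependent post-mobility flight,
   t′ = t_d − c·sqrt(m/z)/1000, with instrument EDC delay coefficient c;
2. reduce each literature CCS for charge and reduced mass,
   Ω′ = Ω / (z·sqrt(1/m + 1/m_gas));
3. fit the power law Ω′ = A·t′^X by least squares in log-log space.

A fitted model then maps (t_d, m/z, z, m) of an unknown to CCS.  The
module also fits the "random-coil" trendline — a log-log regression of
CCS on molecular mass for unstructured peptides — whose percentage
deviations diagnose compaction (negative) or extension (positive), and
reads conformer CCS values off arrival-time profiles by peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .constants import N2_MASS


@dataclass(frozen=True)
class CalibrantEntry:
    """One calibrant ion: mass, charge, measured drift time, known CCS."""

    mass: float  # Da (neutral molecular mass)
    charge: int
    drift_time: float  # ms
    ccs: float  # Å², literature value

    def __post_init__(self) -> None:
        if min(self.mass, self.drift_time, self.ccs) <= 0 or self.charge < 1:
            raise ValueError("calibrant fields must be positive, charge >= 1")

    @property
    def mz(self) -> float:
        from .constants import PROTON

        return (self.mass + self.charge * PROTON) / self.charge


def read_calibrants(path: str | Path) -> list[CalibrantEntry]:
    """Read a delimited calibrant table (mass, charge, drift_time_ms, ccs_A2)."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().split("_")[0]: c for c in df.columns}
    return [
        CalibrantEntry(
            float(r[cols["mass"]]),
            int(r[cols["charge"]]),
            float(r[cols["drift"]]),
            float(r[cols["ccs"]]),
        )
        for _, r in df.iterrows()
    ]


def correct_drift_time(t_d: float, mz: float, c: float) -> float:
    """EDC flight-time correction: t′ = t_d − c·sqrt(m/z)/1000 (ms)."""
    if t_d <= 0:
        raise ValueError("drift time must be positive")
    t = t_d - c * np.sqrt(mz) / 1000.0
    if t <= 0:
        raise ValueError(
            f"corrected drift time {t:.4g} ms <= 0 (EDC coefficient too large)"
        )
    return t


def reduced_ccs(ccs: float, z: int, m: float, m_gas: float = N2_MASS) -> float:
    """Charge/reduced-mass normalized CCS: Ω′ = Ω / (z·sqrt(1/m + 1/m_gas))."""
    if min(ccs, m, m_gas) <= 0 or z < 1:
        raise ValueError("all arguments must be positive, z >= 1")
    return ccs / (z * np.sqrt(1.0 / m + 1.0 / m_gas))


def unreduce_ccs(ccs_prime: float, z: int, m: float, m_gas: float = N2_MASS) -> float:
    """Inverse of :func:`reduced_ccs`."""
    return ccs_prime * z * np.sqrt(1.0 / m + 1.0 / m_gas)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted TW-IMS power-law calibration Ω′ = A·t′^X."""

    edc_coefficient: float
    A: float
    X: float
    gas_mass: float
    r_squared: float

    def ccs(self, t_d: float, mz: float, z: int, m: float) -> float:
        """Map a measured drift time to CCS (Å²)."""
        t = correct_drift_time(t_d, mz, self.edc_coefficient)
        return unreduce_ccs(self.A * t**self.X, z, m, self.gas_mass)


def fit_calibration(
    entries: list[CalibrantEntry],
    edc_coefficient: float,
    gas_mass: float = N2_MASS,
) -> CalibrationModel:
    """Least-squares fit of ln Ω′ on ln t′ over the calibrant set."""
    if len(entries) < 3:
        raise ValueError("calibration needs at least 3 calibrants")
    t = np.array(
        [correct_drift_time(e.drift_time, e.mz, edc_coefficient) for e in entries]
    )
    w = np.array([reduced_ccs(e.ccs, e.charge, e.mass, gas_mass) for e in entries])
    lx, ly = np.log(t), np.log(w)
    X, lnA = np.polyfit(lx, ly, 1)
    resid = ly - (lnA + X * lx)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return CalibrationModel(edc_coefficient, float(np.exp(lnA)), float(X), gas_mass, r2)


def apply_calibration(
    model: CalibrationModel, t_d: float, mz: float, z: int, m: float
) -> float:
    """CCS of an unknown: Ω = A·t′^X · z·sqrt(1/m + 1/m_gas)."""
    return model.ccs(t_d, mz, z, m)


# ---------------------------------------------------------------------------
# random-coil trendline


@dataclass(frozen=True)
class TrendlineModel:
    """Log-log regression of CCS on molecular mass for reference peptides."""

    slope: float
    intercept: float  # ln(CCS) at ln(mass) = 0
    n_points: int

    def predict(self, mass: float) -> float:
        """Random-coil reference CCS Ω_rc(M) in Å²."""
        return float(np.exp(self.intercept + self.slope * np.log(mass)))


def fit_trendline(points: list[tuple[float, float]]) -> TrendlineModel:
    """Fit the random-coil trendline to (mass, ccs) reference points."""
    if len(points) < 3:
        raise ValueError("trendline needs at least 3 points")
    m = np.log([p[0] for p in points])
    c = np.log([p[1] for p in points])
    slope, intercept = np.polyfit(m, c, 1)
    return TrendlineModel(float(slope), float(intercept), len(points))


def delta_to_trendline(ccs: float, mass: float, model: TrendlineModel) -> float:
    """Percent deviation of a measured CCS from the random-coil reference."""
    ref = model.predict(mass)
    return 100.0 * (ccs - ref) / ref


def delta_to_unmod(delta_rc_mod: float, delta_rc_unmod: float) -> float:
    """CCS deviation of a modified peptide relative to its unmodified form.

    Both arguments are trendline deviations (percent); the difference of
    the two removes the trendline reference, leaving the deviation
    attributable to the modification.
    """
    return delta_rc_mod - delta_rc_unmod


# ---------------------------------------------------------------------------
# arrival-time profiles


def detect_conformers(
    axis: np.ndarray,
    intensity: np.ndarray,
    min_rel_height: float = 0.10,
    min_spacing: float = 0.0,
) -> list[float]:
    """Pick conformer peaks off an arrival-time/CCS profile.

    Local maxima above ``min_rel_height`` of the global maximum and at
    least ``min_spacing`` axis units apart; two features closer than the
    spacing merge into the taller one.  Returned in decreasing intensity
    order.
    """
    axis = np.asarray(axis, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(axis) == 0:
        raise ValueError("empty profile")
    step = float(np.median(np.diff(axis))) if len(axis) > 1 else 1.0
    distance = max(1, int(round(min_spacing / step))) if min_spacing else 1
    idx, _ = find_peaks(
        intensity, height=min_rel_height * float(intensity.max()), distance=distance
    )
    order = np.argsort(intensity[idx])[::-1]
    return [float(axis[i]) for i in idx[order]]
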