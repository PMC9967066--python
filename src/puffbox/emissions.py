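"""Total particle emission, emission factors and number-to-mass conversion.

The chamber mass balance inverts measured concentrations into emitted
particles.  Over one sampling interval dt with first-order loss beta,
the concentration carried over from the previous sample is
C(t-dt)*exp(-beta*dt); any excess must have been emitted, so

    TP = sum_i  V_c * ( C(t_i) - C(t_{i-1}) * exp(-beta*dt) )

summed over intervals inside the emission window.  With beta = 0 the
sum telescopes to V_c * (C(t_stop) - C(t_start)).  The emission factor
is the per-puff quotient

    EF = dilution_factor * TP / puff_number,

where the dilution factor (generator flow over chamber flow) rescales
chamber-derived emissions to generator output and defaults to 1 for the
static chamber.  Number emissions convert to mass assuming spherical
particles of density 1 g/cm^3 (PG/VG droplets are near unit density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chamber import ChamberScenario
from .decay import DecayFit
from .grids import SizeGrid
from .series import ConcSeries

G_TO_UG = 1e6
NM_TO_CM = 1e-7


@dataclass(frozen=True)
class EmissionWindow:
    """Time bounds of the emission period fed to the mass balance."""

    t_start_s: float
    t_stop_s: float

    def __post_init__(self) -> None:
        if self.t_stop_s <= self.t_start_s:
            raise ValueError("t_stop_s must exceed t_start_s")


@dataclass(frozen=True)
class MassConversionSpec:
    """Sphere-equivalent mass conversion parameters."""

    density_g_cm3: float = 1.0
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if self.shape != "sphere":
            raise ValueError("only spherical particles are supported")


@dataclass(frozen=True)
class EmissionResult:
    """Emission totals and per-puff factors with their provenance."""

    tp_number: float
    ef_number_per_puff: float
    puff_number: int
    dilution_factor: float
    beta_used_per_s: float
    scenario_label: str
    tp_mass_ug: float = float("nan")
    ef_mass_ug_per_puff: float = float("nan")

    def to_frame(self, device: str = "") -> pd.DataFrame:
        rows = [
            {
                "scenario": self.scenario_label,
                "device": device,
                "metric": "number",
                "tp": self.tp_number,
                "ef_per_puff": self.ef_number_per_puff,
                "puff_number": self.puff_number,
                "dilution_factor": self.dilution_factor,
                "beta_per_s": self.beta_used_per_s,
            }
        ]
        if np.isfinite(self.tp_mass_ug):
            rows.append(
                {
                    "scenario": self.scenario_label,
                    "device": device,
                    "metric": "mass_ug",
                    "tp": self.tp_mass_ug,
                    "ef_per_puff": self.ef_mass_ug_per_puff,
                    "puff_number": self.puff_number,
                    "dilution_factor": self.dilution_factor,
                    "beta_per_s": self.beta_used_per_s,
                }
            )
        return pd.DataFrame(rows)


def _interval_emissions(
    times: np.ndarray,
    conc: np.ndarray,
    volume_cm3: float,
    beta_per_s: float,
    window: EmissionWindow,
    variant: str,
    clip_negative: bool,
) -> np.ndarray:
    dt = times[1] - times[0]
    decay = np.exp(-beta_per_s * dt)
    # interval i spans (t_{i-1}, t_i]; include intervals ending inside the window
    idx = np.arange(1, times.size)
    in_win = (times[idx] > window.t_start_s + 1e-12) & (times[idx] <= window.t_stop_s + 1e-12)
    idx = idx[in_win]
    increments = volume_cm3 * (conc[idx] - conc[idx - 1] * decay)
    if variant == "decay_compensated":
        # alternative reading of the balance with an extra decay divisor
        increments = increments / decay
    elif variant != "reconstruct":
        raise ValueError("variant must be 'reconstruct' or 'decay_compensated'")
    if clip_negative:
        increments = np.clip(increments, 0.0, None)
    return increments


def total_emission(
    series: ConcSeries | tuple[np.ndarray, np.ndarray],
    chamber: ChamberScenario,
    beta: DecayFit | float,
    window: EmissionWindow,
    per_bin: bool = False,
    variant: str = "reconstruct",
    clip_negative: bool = False,
) -> float | np.ndarray:
    """Total particles emitted (#) inside the window, loss-corrected.

    ``per_bin=True`` returns the per-bin vector of emitted particles
    (requires a ConcSeries); its sum equals the total-trace estimate
    because the balance is linear in concentration.
    """
    beta_val = beta.beta_per_s if isinstance(beta, DecayFit) else float(beta)
    if beta_val < 0:
        raise ValueError("beta must be >= 0 for emission reconstruction")
    if isinstance(series, ConcSeries):
        times = series.times
        mat = series.conc
    else:
        times, tot = series
        times = np.asarray(times, dtype=float)
        mat = np.asarray(tot, dtype=float)[:, None]
        if per_bin:
            raise ValueError("per_bin requires a ConcSeries")
    diffs = np.diff(times)
    if not np.allclose(diffs, diffs[0], rtol=1e-9):
        raise ValueError("total_emission requires uniform sampling intervals")
    if window.t_start_s < times[0] - 1e-9 or window.t_stop_s > times[-1] + 1e-9:
        raise ValueError("emission window lies outside the series")
    per_bin_tp = np.array(
        [
            _interval_emissions(
                times, mat[:, b], chamber.volume_cm3, beta_val, window, variant, clip_negative
            ).sum()
            for b in range(mat.shape[1])
        ]
    )
    if per_bin and isinstance(series, ConcSeries):
        return per_bin_tp
    return float(per_bin_tp.sum())


def default_emission_window(
    series: ConcSeries, puff_times_s: np.ndarray, lag_s: float = 120.0
) -> EmissionWindow:
    """Window rule: one sample before the first puff to last puff + lag."""
    puff_times_s = np.asarray(puff_times_s, dtype=float)
    if puff_times_s.size == 0:
        raise ValueError("no puffs")
    start = max(float(series.times[0]), float(puff_times_s[0]) - series.dt_s)
    stop = min(float(series.times[-1]), float(puff_times_s[-1]) + lag_s)
    return EmissionWindow(start, stop)


def emission_factor(
    tp: float,
    puff_number: int,
    dilution_factor: float = 1.0,
    beta_used_per_s: float = float("nan"),
    scenario_label: str = "static",
    tp_mass_ug: float = float("nan"),
) -> EmissionResult:
    """Per-puff emission factor EF = dilution_factor * TP / puff_number."""
    if puff_number < 1:
        raise ValueError("puff_number must be >= 1")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    ef_n = dilution_factor * tp / puff_number
    ef_m = dilution_factor * tp_mass_ug / puff_number if np.isfinite(tp_mass_ug) else float("nan")
    return EmissionResult(
        tp_number=float(tp),
        ef_number_per_puff=float(ef_n),
        puff_number=int(puff_number),
        dilution_factor=float(dilution_factor),
        beta_used_per_s=float(beta_used_per_s),
        scenario_label=scenario_label,
        tp_mass_ug=float(tp_mass_ug),
        ef_mass_ug_per_puff=float(ef_m),
    )


def number_to_mass(
    per_bin_counts: np.ndarray, grid: SizeGrid, spec: MassConversionSpec | None = None
) -> float:
    """Convert per-bin particle counts to total mass in micrograms.

    Each particle in a bin is a sphere at the geometric bin midpoint:
    m = (pi/6) d_mid^3 rho with d_mid in cm and rho in g/cm^3.
    """
    spec = spec if spec is not None else MassConversionSpec()
    counts = np.asarray(per_bin_counts, dtype=float)
    if counts.shape != (grid.n_bins,):
        raise ValueError(
            f"counts length {counts.shape} does not match grid bins ({grid.n_bins})"
        )
    d_cm = grid.bin_mids * NM_TO_CM
    mass_g = np.sum(counts * (np.pi / 6.0) * d_cm**3 * spec.density_g_cm3)
    return float(mass_g * G_TO_UG)


def scenario_ratio(
    ef_a: float, ef_b: float, metric_a: str = "", metric_b: str = "", rounding: str = "none"
) -> float:
    """Ratio of two emission factors, optionally rounded to nearest int.

    Used to compare ventilation scenarios (e.g. unventilated over
    ventilated EF).  Metric labels, when given, must match: comparing a
    number EF against a mass EF is rejected.
    """
    if metric_a != metric_b:
        raise ValueError(f"metric mismatch: {metric_a!r} vs {metric_b!r}")
    if ef_b <= 0:
        raise ValueError("denominator EF must be positive")
    ratio = ef_a / ef_b
    if rounding == "nearest_int":
        return float(round(ratio))
    if rounding != "none":
        raise ValueError("rounding must be 'none' or 'nearest_int'")
    return float(ratio)
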