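"""Well-mixed exposure-chamber forward model and instrument emulation.

The chamber is a single well-mixed volume V_c receiving per-puff aerosol
injections.  Each size bin independently obeys the box-model balance

    dC/dt = S(t)/V_c - (lambda + beta_dep) * C,

with lambda = ACH/3600 the ventilation rate in 1/s and beta_dep a
first-order deposition rate.  A puff enters as an instantaneous
well-mixed impulse E_bin/V_c at its scheduled time — the 3 s puff and
the 1 L pre-mixing volume are far shorter/smaller than chamber time
scales — so between puffs every bin decays as a pure exponential and
the solution is analytic per interval.

This module doubles as the synthetic-data generator: its defaults
emulate the study conditions of a 6 m^3 stainless-steel chamber run
either static (0 ACH, mixing fan) for small puff numbers or dynamic
(3 1/h ACH) for large ones, sampled by SMPS+OPS-like instruments with
an OPS detection ceiling of 3000 #/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import SizeGrid, composite_grid, concat_edges
from .puffs import PuffSchedule
from .series import ConcSeries
from .sizedist import LognormalMode, discretize_mode

OPS_CEILING_PER_CM3 = 3000.0  # optical sizer maximum detection limit
M3_TO_CM3 = 1e6


@dataclass(frozen=True)
class ChamberScenario:
    """Chamber volume, ventilation and dilution flows for one scenario.

    ``static`` is the unventilated room scenario (0 ACH, mixing fan);
    ``dynamic`` runs at a positive air-exchange rate (default study
    value 3 1/h) with part of the generator output diverted to other
    sampling, so a dilution factor > 1 rescales chamber-derived
    emissions back to generator output.
    """

    volume_Vc_m3: float = 6.0
    ach: float = 0.0
    label: str = "static"
    dilution_flow_eags_lpm: float | None = None
    dilution_flow_chamber_lpm: float | None = None

    def __post_init__(self) -> None:
        if self.volume_Vc_m3 <= 0:
            raise ValueError("chamber volume must be positive")
        if self.ach < 0:
            raise ValueError("ACH must be >= 0")
        if self.label not in ("static", "dynamic"):
            raise ValueError("label must be 'static' or 'dynamic'")
        if self.label == "static" and self.ach != 0:
            raise ValueError("static scenario requires ach = 0")
        if self.label == "dynamic" and self.ach <= 0:
            raise ValueError("dynamic scenario requires ach > 0")

    @property
    def volume_cm3(self) -> float:
        return self.volume_Vc_m3 * M3_TO_CM3

    @property
    def lambda_per_s(self) -> float:
        """Ventilation loss rate, ACH converted to 1/s."""
        return self.ach / 3600.0

    @property
    def dilution_factor(self) -> float:
        """Generator-to-chamber flow ratio; 1 when no flow is diverted."""
        if self.dilution_flow_eags_lpm is None or self.dilution_flow_chamber_lpm is None:
            return 1.0
        if self.dilution_flow_eags_lpm <= 0 or self.dilution_flow_chamber_lpm <= 0:
            raise ValueError("dilution flows must be positive when specified")
        return self.dilution_flow_eags_lpm / self.dilution_flow_chamber_lpm


@dataclass(frozen=True)
class SourceSpec:
    """Per-puff emitted size distribution: lognormal modes + total number.

    Mode ``n_total`` values are interpreted as number weights and must
    sum to 1; ``number_per_puff`` carries the absolute emission.
    """

    modes: tuple[LognormalMode, ...]
    number_per_puff: float

    def __post_init__(self) -> None:
        if self.number_per_puff <= 0:
            raise ValueError("number_per_puff must be positive")
        if not self.modes:
            raise ValueError("at least one mode required")
        wsum = sum(m.n_total for m in self.modes)
        if not np.isclose(wsum, 1.0, rtol=1e-9):
            raise ValueError(f"mode weights must sum to 1, got {wsum}")
        object.__setattr__(self, "modes", tuple(self.modes))

    def per_bin_emission(self, grid: SizeGrid) -> np.ndarray:
        """Particles emitted per puff in each bin (# / puff)."""
        out = np.zeros(grid.n_bins)
        for m in self.modes:
            out += discretize_mode(
                LognormalMode(m.n_total * self.number_per_puff, m.gmd_nm, m.gsd), grid
            )
        return out


def pod_source(number_per_puff: float = 4.92e10) -> SourceSpec:
    """Pod-type default source: one mode near 100 nm."""
    return SourceSpec((LognormalMode(1.0, 100.0, 1.7),), number_per_puff)


def mod_source(number_per_puff: float = 1.72e10) -> SourceSpec:
    """Mod-type default source: Aitken (58.2 nm) + accumulation (794 nm).

    Number is dominated by the Aitken mode and mass by the accumulation
    mode, matching the bimodal character of sub-ohm devices.
    """
    return SourceSpec(
        (LognormalMode(0.97, 58.2, 1.6), LognormalMode(0.03, 794.0, 1.6)),
        number_per_puff,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument noise: multiplicative lognormal, optional Poisson counts.

    ``gsd`` is the geometric standard deviation of the multiplicative
    component (1.0 disables it).  Poisson resampling emulates counting
    statistics given an effective sample volume per reading.
    """

    gsd: float = 1.05
    poisson: bool = False
    sample_volume_cm3: float = 16.7  # ~1 LPM over a 1 s reading

    def __post_init__(self) -> None:
        if self.gsd < 1.0:
            raise ValueError("noise gsd must be >= 1")
        if self.sample_volume_cm3 <= 0:
            raise ValueError("sample volume must be positive")

    def apply(self, conc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = conc
        if self.gsd > 1.0:
            sigma = np.log(self.gsd)
            out = out * rng.lognormal(0.0, sigma, size=conc.shape)
        if self.poisson:
            counts = rng.poisson(out * self.sample_volume_cm3)
            out = counts / self.sample_volume_cm3
        return out


def simulate_chamber(
    scenario: ChamberScenario,
    schedule: PuffSchedule,
    source: SourceSpec,
    beta_dep_per_s: float | np.ndarray = 0.0,
    dt_s: float = 10.0,
    t_end_s: float | None = None,
    grid: SizeGrid | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    initial_conc: np.ndarray | None = None,
) -> ConcSeries:
    """Simulate size-resolved chamber concentrations for a puff schedule.

    Returns concentrations sampled at 0, dt, 2*dt, ... up to ``t_end_s``
    (default: last puff + one hour).  ``beta_dep_per_s`` may be a scalar
    or a per-bin vector to emulate faster loss of a large-particle mode.
    Identical seed and inputs give bit-identical output.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    grid = grid if grid is not None else composite_grid()
    beta = np.broadcast_to(np.asarray(beta_dep_per_s, dtype=float), (grid.n_bins,))
    if np.any(beta < 0):
        raise ValueError("beta_dep must be >= 0")
    if t_end_s is None:
        last = schedule.puff_times_s[-1] if schedule.n_puffs else 0.0
        t_end_s = last + 3600.0
    if schedule.n_puffs and schedule.puff_times_s[-1] > t_end_s:
        raise ValueError("puff times must lie within the simulation horizon")
    if schedule.n_puffs and schedule.puff_times_s[0] < 0:
        raise ValueError("puff times must be >= 0")

    n_steps = int(np.floor(t_end_s / dt_s + 1e-9)) + 1
    times = dt_s * np.arange(n_steps)
    k = scenario.lambda_per_s + beta  # total first-order loss per bin

    conc = np.zeros((n_steps, grid.n_bins))
    if initial_conc is not None:
        c0 = np.asarray(initial_conc, dtype=float)
        if c0.shape != (grid.n_bins,):
            raise ValueError("initial_conc must have one value per bin")
        conc += c0[None, :] * np.exp(-np.outer(times, k))
    if schedule.n_puffs:
        step_bins = source.per_bin_emission(grid) / scenario.volume_cm3
        for t_p in schedule.puff_times_s:
            elapsed = times - t_p
            mask = elapsed >= 0
            conc[mask] += step_bins[None, :] * np.exp(-np.outer(elapsed[mask], k))

    if noise is not None and (noise.gsd > 1.0 or noise.poisson):
        rng = np.random.default_rng(seed)
        conc = noise.apply(conc, rng)

    return ConcSeries(times, grid, conc)


def apply_instrument(series: ConcSeries, ceiling_per_cm3: float = OPS_CEILING_PER_CM3) -> ConcSeries:
    """Clip concentrations at an instrument detection ceiling and flag them."""
    if not ceiling_per_cm3 > 0:
        raise ValueError("ceiling must be positive")
    flagged = series.conc >= ceiling_per_cm3
    clipped = np.minimum(series.conc, ceiling_per_cm3)
    return ConcSeries(
        series.times.copy(), series.grid, clipped, series.saturated | flagged
    )


def stitch_grids(smps: ConcSeries, ops: ConcSeries) -> ConcSeries:
    """Concatenate SMPS and OPS series into one composite series.

    Requires identical timestamps and grids abutting at 300 nm; the
    stitched total concentration is the sum of both instruments' totals
    by construction.
    """
    if smps.times.shape != ops.times.shape or not np.allclose(
        smps.times, ops.times, rtol=0, atol=1e-9
    ):
        raise ValueError("instrument series must share identical timestamps")
    edges = concat_edges(smps.grid, ops.grid)
    grid = SizeGrid(edges, "composite")
    return ConcSeries(
        smps.times.copy(),
        grid,
        np.hstack([smps.conc, ops.conc]),
        np.hstack([smps.saturated, ops.saturated]),
    )
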