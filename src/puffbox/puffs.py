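"""Puff topography, schedules, puff fractions and device power model.

The square-wave puff profile follows the CORESTA Recommended Method
No. 81 machine-vaping convention (55 mL drawn over 3 s, i.e. a mean flow
of 1.1 LPM).  Puff fractions segment a pod cartridge's lifetime into
initial (puffs 1-50), middle (51-100) and late (101-150) thirds, after
which the cartridge is near depletion.  Coil power declines with device
ageing; the decline is summarized by an ordinary-least-squares line in
puff index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FRACTION_BOUNDS: dict[str, tuple[int, int]] = {
    "initial": (1, 50),
    "middle": (51, 100),
    "late": (101, 150),
}


@dataclass(frozen=True)
class PuffProfile:
    """Machine-puff profile: a square wave of given volume and duration."""

    volume_mL: float = 55.0
    duration_s: float = 3.0
    shape: str = "square"

    def __post_init__(self) -> None:
        if self.shape != "square":
            raise ValueError("only square puff profiles are supported")
        if self.volume_mL <= 0:
            raise ValueError("puff volume must be positive")
        if self.duration_s <= 0:
            raise ValueError("puff duration must be positive")


def mean_flow_lpm(profile: PuffProfile) -> float:
    """Mean volumetric flow of the square puff in litres per minute.

    The 55 mL / 3 s CORESTA profile gives exactly 1.1 LPM.
    """
    return profile.volume_mL / profile.duration_s * 60.0 / 1000.0


@dataclass(frozen=True)
class PuffSchedule:
    """Times at which puffs are delivered, with the shared puff profile."""

    puff_times_s: np.ndarray
    profile: PuffProfile = field(default_factory=PuffProfile)
    fraction_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_BOUNDS)
    )

    def __post_init__(self) -> None:
        times = np.asarray(self.puff_times_s, dtype=float)
        if times.ndim != 1:
            raise ValueError("puff_times_s must be 1-d")
        if times.size and np.any(np.diff(times) < self.profile.duration_s):
            raise ValueError("inter-puff gaps must be at least the puff duration")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("puff times must be strictly increasing")
        object.__setattr__(self, "puff_times_s", times)

    @property
    def n_puffs(self) -> int:
        return self.puff_times_s.size

    @property
    def puff_rate_per_min(self) -> float:
        """Mean puffing rate over the span of the schedule."""
        if self.n_puffs < 2:
            raise ValueError("need >= 2 puffs to define a rate")
        span = self.puff_times_s[-1] - self.puff_times_s[0]
        return (self.n_puffs - 1) / span * 60.0

    def to_csv(self, path, power_W: np.ndarray | None = None) -> None:
        df = pd.DataFrame(
            {
                "puff_index": np.arange(1, self.n_puffs + 1),
                "puff_time_s": self.puff_times_s,
            }
        )
        if power_W is not None:
            df["power_W"] = np.asarray(power_W, dtype=float)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, profile: PuffProfile | None = None) -> "PuffSchedule":
        df = pd.read_csv(path)
        return cls(
            df["puff_time_s"].to_numpy(dtype=float),
            profile if profile is not None else PuffProfile(),
        )


def regular_schedule(
    n_puffs: int, interval_s: float, start_s: float = 0.0, profile: PuffProfile | None = None
) -> PuffSchedule:
    """Evenly spaced puffs: ``n_puffs`` starting at ``start_s``."""
    if n_puffs < 1:
        raise ValueError("n_puffs must be >= 1")
    times = start_s + interval_s * np.arange(n_puffs)
    return PuffSchedule(times, profile if profile is not None else PuffProfile())


def label_fraction(
    puff_index: int, bounds: dict[str, tuple[int, int]] | None = None
) -> str:
    """Map a 1-based puff index to its lifetime fraction label.

    Ranges are inclusive on both ends: puff 50 is ``initial``, 51
    ``middle``.
    """
    bounds = bounds if bounds is not None else DEFAULT_FRACTION_BOUNDS
    for label, (lo, hi) in bounds.items():
        if lo <= puff_index <= hi:
            return label
    raise ValueError(f"puff index {puff_index} is outside all fraction ranges")


@dataclass(frozen=True)
class DeviceConfig:
    """Atomizer/e-liquid configuration of one vaping experiment."""

    device_type: str  # {pod, mod}
    coil_resistance_ohm: float
    power_W: float
    flavor: str = ""
    nicotine_pct: float = 0.0
    pg_vg: str = ""

    def __post_init__(self) -> None:
        if self.device_type not in ("pod", "mod"):
            raise ValueError("device_type must be 'pod' or 'mod'")
        if self.coil_resistance_ohm <= 0:
            raise ValueError("coil resistance must be positive")
        if self.power_W <= 0:
            raise ValueError("power must be positive")


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float


@dataclass(frozen=True)
class PowerTrace:
    """Per-puff coil power, optionally with its fitted ageing line."""

    puff_index: np.ndarray
    power_W: np.ndarray
    linear_fit: LinearFit | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.puff_index, dtype=float)
        p = np.asarray(self.power_W, dtype=float)
        if idx.shape != p.shape or idx.ndim != 1:
            raise ValueError("puff_index and power_W must be 1-d and equal length")
        if np.any(p <= 0):
            raise ValueError("power values must be positive")
        object.__setattr__(self, "puff_index", idx)
        object.__setattr__(self, "power_W", p)


def fit_power_trace(trace: PowerTrace) -> PowerTrace:
    """OLS line power_W ~ puff_index describing the ageing power decline."""
    if trace.puff_index.size < 2 or np.unique(trace.puff_index).size < 2:
        raise ValueError("need >= 2 distinct puff indices to fit a line")
    res = stats.linregress(trace.puff_index, trace.power_W)
    resid = trace.power_W - (res.intercept + res.slope * trace.puff_index)
    fit = LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=float(np.std(resid, ddof=2)) if resid.size > 2 else 0.0,
    )
    return replace(trace, linear_fit=fit)


def simulate_power_trace(
    n_puffs: int = 150,
    intercept_W: float = 7.0,
    slope_W_per_puff: float = -0.004,
    noise_sd_W: float = 0.0,
    seed: int | None = None,
) -> PowerTrace:
    """Synthesize a linearly declining per-puff power trace.

    Defaults emulate a 7 W pod coil losing a few percent of its power
    over a 150-puff lifetime.
    """
    idx = np.arange(1, n_puffs + 1, dtype=float)
    power = intercept_W + slope_W_per_puff * idx
    if noise_sd_W > 0:
        rng = np.random.default_rng(seed)
        power = power + rng.normal(0.0, noise_sd_W, size=n_puffs)
    if np.any(power <= 0):
        raise ValueError("simulated power went non-positive; adjust slope/intercept")
    return PowerTrace(idx, power)


def correlate_power_ef(
    per_fraction_power: np.ndarray, per_fraction_mass_ef: np.ndarray
) -> float:
    """Pearson correlation between per-fraction coil power and mass EF."""
    p = np.asarray(per_fraction_power, dtype=float)
    m = np.asarray(per_fraction_mass_ef, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or p.size < 3:
        raise ValueError("inputs must be equal-length 1-d arrays with >= 3 points")
    if np.ptp(p) == 0 or np.ptp(m) == 0:
        raise ValueError("zero variance in an input; correlation undefined")
    r, _ = stats.pearsonr(p, m)
    return float(r)
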