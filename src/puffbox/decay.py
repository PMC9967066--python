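"""First-order loss-coefficient estimation from post-vaping decay.

After the last puff, a well-mixed chamber's total concentration decays
as C(t) = C0 * exp(-beta t) where beta lumps ventilation and deposition.
beta is estimated as minus the slope of an ordinary-least-squares
regression of ln C on t over a user- or rule-chosen window; for a clean
exponential the log-linear fit is exact.  A nonlinear least-squares
alternative (direct exponential fit) is available behind a flag for
noisy traces where log transformation would bias the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .puffs import PuffSchedule
from .series import ConcSeries


@dataclass(frozen=True)
class DecayFit:
    """Estimated loss coefficient with its fit window and diagnostics.

    ``beta_per_s`` is the first-order loss rate in 1/s.  ``r_squared``
    is NaN-flagged when undefined (constant trace).  A negative estimate
    (growing concentration) is kept but ``physical`` is False.
    """

    beta_per_s: float
    window: tuple[float, float]
    r_squared: float
    n_points: int
    c0: float = float("nan")

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed window start")
        if self.n_points < 3:
            raise ValueError("a decay fit needs at least 3 samples")

    @property
    def physical(self) -> bool:
        return self.beta_per_s >= 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta_per_s": [self.beta_per_s],
                "window_begin_s": [self.window[0]],
                "window_end_s": [self.window[1]],
                "r_squared": [self.r_squared],
                "n_points": [self.n_points],
            }
        )


def _as_total(series: ConcSeries | tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, ConcSeries):
        return series.times, series.total()
    times, conc = series
    return np.asarray(times, dtype=float), np.asarray(conc, dtype=float)


def fit_decay(
    series: ConcSeries | tuple[np.ndarray, np.ndarray],
    window: tuple[float, float],
    per_bin: bool = False,
    nonlinear: bool = False,
) -> DecayFit | list[DecayFit]:
    """Estimate the loss coefficient from concentration decay in a window.

    Parameters
    ----------
    series
        A :class:`ConcSeries` (total over bins is fitted) or a
        ``(times, concentrations)`` pair.
    window
        ``(t_begin, t_end)`` in seconds; samples with
        ``t_begin <= t <= t_end`` are used.  All concentrations in the
        window must be positive.
    per_bin
        Fit each size channel separately (requires a ConcSeries);
        returns a list of fits.
    nonlinear
        Use direct exponential least squares instead of log-linear OLS.
    """
    if per_bin:
        if not isinstance(series, ConcSeries):
            raise ValueError("per_bin fitting requires a ConcSeries")
        return [
            fit_decay((series.times, series.conc[:, b]), window, nonlinear=nonlinear)
            for b in range(series.grid.n_bins)
        ]
    times, conc = _as_total(series)
    t0, t1 = window
    mask = (times >= t0) & (times <= t1)
    t = times[mask]
    c = conc[mask]
    if t.size < 3:
        raise ValueError(f"fewer than 3 samples in window [{t0}, {t1}]")
    if np.any(c <= 0):
        raise ValueError("window contains non-positive concentrations")

    if np.allclose(c, c[0], rtol=1e-12):
        # constant trace: zero loss, goodness-of-fit undefined
        return DecayFit(0.0, (t0, t1), float("nan"), int(t.size), float(c[0]))

    if nonlinear:
        lr = stats.linregress(t, np.log(c))

        def model(tt: np.ndarray, c0: float, beta: float) -> np.ndarray:
            return c0 * np.exp(-beta * tt)

        popt, _ = optimize.curve_fit(
            model, t, c, p0=[float(np.exp(lr.intercept)), float(-lr.slope)], maxfev=10000
        )
        resid = c - model(t, *popt)
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
        return DecayFit(float(popt[1]), (t0, t1), r2, int(t.size), float(popt[0]))

    lr = stats.linregress(t, np.log(c))
    return DecayFit(
        float(-lr.slope),
        (t0, t1),
        float(lr.rvalue**2),
        int(t.size),
        float(np.exp(lr.intercept)),
    )


def pick_decay_window(
    series: ConcSeries, schedule: PuffSchedule, lag_s: float = 120.0
) -> tuple[float, float]:
    """Window rule: from last puff + mixing lag to the series end,
    truncated before the first saturated sample inside the window."""
    if schedule.n_puffs == 0:
        raise ValueError("schedule has no puffs")
    t_begin = float(schedule.puff_times_s[-1]) + lag_s
    t_end = float(series.times[-1])
    if t_end <= t_begin:
        raise ValueError("series does not extend beyond the last puff + lag")
    sat_rows = series.saturated.any(axis=1)
    in_window = (series.times >= t_begin) & sat_rows
    if in_window.any():
        first_sat = float(series.times[in_window][0])
        t_end = first_sat - series.dt_s
        if t_end <= t_begin:
            raise ValueError("no unsaturated post-puff data to fit")
    return (t_begin, t_end)
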