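"""Lognormal size-distribution normalization, moments and mode fitting.

Aerosol number size distributions are conventionally expressed as
dN/dlogDp, the concentration per decade of diameter, so that instrument
grids with different bin widths are comparable.  E-cigarette aerosol is
well described by one or two lognormal modes: pod-type devices emit a
single mode near 100 nm, while sub-ohm mod-type devices add an
accumulation mode near 800 nm alongside an Aitken mode near 60 nm.

A mode with geometric mean diameter GMD and geometric standard
deviation GSD contributes

    dN/dlogDp(Dp) = N / (sqrt(2 pi) log10 GSD)
                    * exp(-(log10 Dp - log10 GMD)^2 / (2 log10^2 GSD))

and the mixture fit minimizes least squares of the model against the
binned dN/dlogDp evaluated at bin midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .grids import SizeGrid

__all__ = [
    "LognormalMode",
    "SizeDistribution",
    "normalize",
    "denormalize",
    "gmd_gsd",
    "fit_modes",
    "ModeFitResult",
    "discretize_mode",
]


@dataclass(frozen=True)
class LognormalMode:
    """One lognormal mode: total number, GMD (nm) and GSD."""

    n_total: float
    gmd_nm: float
    gsd: float

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ValueError("mode number concentration must be >= 0")
        if self.gmd_nm <= 0:
            raise ValueError("GMD must be positive")
        if self.gsd < 1:
            raise ValueError("GSD must be >= 1")

    def dndlogdp(self, d_nm: np.ndarray) -> np.ndarray:
        """Evaluate the mode's dN/dlogDp at diameters ``d_nm``."""
        s = np.log10(self.gsd)
        if s == 0:  # monodisperse limit has no density representation
            raise ValueError("dndlogdp undefined for GSD = 1 (monodisperse)")
        x = np.log10(np.asarray(d_nm, dtype=float))
        mu = np.log10(self.gmd_nm)
        return self.n_total / (np.sqrt(2 * np.pi) * s) * np.exp(-((x - mu) ** 2) / (2 * s**2))


def discretize_mode(mode: LognormalMode, grid: SizeGrid, renormalize: bool = True) -> np.ndarray:
    """Per-bin counts of a lognormal mode on a grid.

    Integrates the lognormal number CDF across each bin.  With
    ``renormalize`` the within-grid probabilities are rescaled to sum to
    one so the grid carries exactly ``n_total`` particles (truncation to
    the instrument range conserves number).
    """
    from scipy.stats import norm

    s = np.log(mode.gsd)
    edges = np.log(grid.bin_edges)
    mu = np.log(mode.gmd_nm)
    if s == 0:
        # all particles into the bin containing the GMD
        counts = np.zeros(grid.n_bins)
        idx = np.searchsorted(grid.bin_edges, mode.gmd_nm, side="right") - 1
        idx = min(max(idx, 0), grid.n_bins - 1)
        counts[idx] = mode.n_total
        return counts
    cdf = norm.cdf(edges, loc=mu, scale=s)
    probs = np.diff(cdf)
    if renormalize:
        total = probs.sum()
        if total <= 0:
            raise ValueError("mode lies entirely outside the grid")
        probs = probs / total
    return mode.n_total * probs


@dataclass
class SizeDistribution:
    """Binned dN/dlogDp on a size grid."""

    grid: SizeGrid
    dN_dlogDp: np.ndarray
    total_n: float = field(init=False)

    def __post_init__(self) -> None:
        self.dN_dlogDp = np.asarray(self.dN_dlogDp, dtype=float)
        if self.dN_dlogDp.shape != (self.grid.n_bins,):
            raise ValueError("dN_dlogDp length must match grid bins")
        if np.any(self.dN_dlogDp < 0):
            raise ValueError("dN_dlogDp must be non-negative")
        self.total_n = float(np.sum(self.dN_dlogDp * self.grid.dlog10))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"d_mid_nm": self.grid.bin_mids, "dN_dlogDp": self.dN_dlogDp}
        ).to_csv(path, index=False, float_format="%.17g")


def normalize(counts: np.ndarray, grid: SizeGrid) -> SizeDistribution:
    """Per-bin counts N -> dN/dlogDp = N / log10(edge_hi/edge_lo)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (grid.n_bins,):
        raise ValueError("counts length must match grid bins")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    widths = grid.dlog10
    if np.any(widths <= 0):
        raise ValueError("zero-width bins")
    return SizeDistribution(grid, counts / widths)


def denormalize(dist: SizeDistribution) -> np.ndarray:
    """Inverse of :func:`normalize`: recover per-bin counts."""
    return dist.dN_dlogDp * dist.grid.dlog10


def gmd_gsd(dist: SizeDistribution) -> tuple[float, float]:
    """Moment estimates of GMD (nm) and GSD from a binned distribution.

    Weights are per-bin counts at geometric bin midpoints:
    GMD = exp(sum w ln d_mid), GSD = exp(weighted sd of ln d_mid).
    """
    counts = denormalize(dist)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty distribution")
    w = counts / total
    ln_d = np.log(dist.grid.bin_mids)
    mu = np.sum(w * ln_d)
    var = np.sum(w * (ln_d - mu) ** 2)
    return float(np.exp(mu)), float(np.exp(np.sqrt(var)))


@dataclass(frozen=True)
class ModeFitResult:
    """Fitted lognormal mixture with diagnostics."""

    modes: tuple[LognormalMode, ...]
    converged: bool
    rss: float
    bic: float
    n_modes_tried: tuple[int, ...] = ()
    message: str = ""


def _mixture(d_nm: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(np.asarray(d_nm, dtype=float))
    for i in range(0, len(params), 3):
        n, gmd, gsd = params[i : i + 3]
        out = out + LognormalMode(max(n, 0.0), max(gmd, 1e-3), max(gsd, 1.0001)).dndlogdp(d_nm)
    return out


def _bic(n_obs: int, rss: float, k_params: int) -> float:
    # Gaussian-error BIC; guard rss of numerically perfect fits
    rss = max(rss, 1e-300)
    return n_obs * np.log(rss / n_obs) + k_params * np.log(n_obs)


def _initial_guess(dist: SizeDistribution, n_modes: int) -> list[float]:
    """Deterministic seeds: moments for 1 mode; split at the largest
    internal minimum of the smoothed curve for 2, falling back to
    quantile-based halves."""
    d = dist.grid.bin_mids
    y = dist.dN_dlogDp
    if n_modes == 1:
        gmd, gsd = gmd_gsd(dist)
        return [dist.total_n, gmd, max(gsd, 1.05)]
    # smooth with a short moving average to find an internal minimum
    kernel = np.ones(3) / 3.0
    ys = np.convolve(y, kernel, mode="same")
    split_idx = None
    interior = range(1, len(ys) - 1)
    minima = [i for i in interior if ys[i] <= ys[i - 1] and ys[i] <= ys[i + 1] and ys[i] < ys.max() * 0.9]
    if minima:
        # deepest internal minimum flanked by mass on both sides
        candidates = [i for i in minima if y[:i].sum() > 0 and y[i + 1 :].sum() > 0]
        if candidates:
            split_idx = min(candidates, key=lambda i: ys[i])
    if split_idx is None:
        # quantile fallback: split at the count median
        counts = denormalize(dist)
        csum = np.cumsum(counts)
        split_idx = int(np.searchsorted(csum, csum[-1] / 2))
        split_idx = min(max(split_idx, 1), len(y) - 2)
    guess: list[float] = []
    for sl in (slice(None, split_idx + 1), slice(split_idx, None)):
        sub = SizeDistribution(
            SizeGrid(dist.grid.bin_edges[sl.start or 0 : (sl.stop or dist.grid.n_bins) + 1]),
            y[sl],
        )
        if sub.total_n <= 0:
            gmd = float(d[sl][len(d[sl]) // 2])
            guess += [dist.total_n / 2, gmd, 1.5]
        else:
            gmd, gsd = gmd_gsd(sub)
            guess += [sub.total_n, gmd, min(max(gsd, 1.1), 2.5)]
    return guess


def _fit_k(dist: SizeDistribution, k: int) -> ModeFitResult:
    d = dist.grid.bin_mids
    y = dist.dN_dlogDp
    lower = [0.0, dist.grid.bin_edges[0] * 0.5, 1.01] * k
    upper = [np.inf, dist.grid.bin_edges[-1] * 2.0, 4.0] * k
    p0 = np.clip(_initial_guess(dist, k), lower, upper)
    try:
        popt, _ = optimize.curve_fit(
            _mixture, d, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        converged, message = True, ""
    except RuntimeError as exc:  # non-convergence is reported, never silent
        popt, converged, message = np.array(p0), False, str(exc)
    resid = y - _mixture(d, *popt)
    rss = float(np.sum(resid**2))
    modes = tuple(
        sorted(
            (
                LognormalMode(float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
                for i in range(0, 3 * k, 3)
            ),
            key=lambda m: m.gmd_nm,
        )
    )
    return ModeFitResult(modes, converged, rss, _bic(len(y), rss, 3 * k), (k,), message)


def fit_modes(dist: SizeDistribution, n_modes: int | str = "auto") -> ModeFitResult:
    """Fit a 1- or 2-mode lognormal mixture to a binned distribution.

    ``n_modes='auto'`` fits both and selects by BIC.  Modes are returned
    sorted by GMD.  Non-convergence is flagged in the result, with the
    solver message attached.
    """
    if dist.total_n <= 0:
        raise ValueError("cannot fit modes to an all-zero distribution")
    if n_modes == "auto":
        fit1, fit2 = _fit_k(dist, 1), _fit_k(dist, 2)
        best = fit1
        # second mode needs very strong evidence (Kass-Raftery dBIC >= 10)
        if fit2.converged and (fit1.bic - fit2.bic >= 10.0 or not fit1.converged):
            # a second mode must be genuinely resolved, not a refinement
            # of one lognormal: require separation and a non-trivial share
            g_lo, g_hi = (m.gmd_nm for m in fit2.modes)
            sep_decades = abs(np.log10(g_hi / g_lo))
            n_tot = sum(m.n_total for m in fit2.modes)
            share = min(m.n_total for m in fit2.modes) / n_tot if n_tot > 0 else 0.0
            if sep_decades >= 0.25 and share >= 0.02:
                best = fit2
        return ModeFitResult(
            best.modes, best.converged, best.rss, best.bic, (1, 2), best.message
        )
    k = int(n_modes)
    if k not in (1, 2):
        raise ValueError("n_modes must be 1, 2 or 'auto'")
    informative = int(np.sum(dist.dN_dlogDp > 0))
    if informative < 2 * 3 * k:
        raise ValueError(
            f"need >= {2 * 3 * k} informative bins for a {k}-mode fit, have {informative}"
        )
    return _fit_k(dist, k)


def modes_to_csv(result: ModeFitResult, path) -> None:
    pd.DataFrame(
        {
            "mode": np.arange(1, len(result.modes) + 1),
            "n_total": [m.n_total for m in result.modes],
            "gmd_nm": [m.gmd_nm for m in result.modes],
            "gsd": [m.gsd for m in result.modes],
            "converged": [result.converged] * len(result.modes),
        }
    ).to_csv(path, index=False, float_format="%.17g")
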