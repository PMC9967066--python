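"""Time x size-bin concentration series and its CSV round-trip.

:class:`ConcSeries` is the central measurement object: number
concentration (#/cm^3) on a uniform time axis, one column per diameter
bin, with a boolean saturation mask marking samples at or above an
instrument detection ceiling.

CSV layout: header ``time_s,bin_<lo>nm_<hi>nm,...``, one row per
timestamp; the grid round-trips exactly from the header names.  The
saturation mask travels in a sidecar CSV of 0/1 flags with the same
shape.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import SizeGrid

_BIN_RE = re.compile(r"^bin_(?P<lo>[0-9.eE+-]+)nm_(?P<hi>[0-9.eE+-]+)nm$")


@dataclass
class ConcSeries:
    """Size-resolved number-concentration time series.

    Attributes
    ----------
    times
        Seconds from run start, uniformly spaced, strictly increasing.
    grid
        The diameter bin grid.
    conc
        Concentration matrix ``[n_times, n_bins]`` in #/cm^3, >= 0.
    saturated
        Boolean matrix, True where the value sat at/above an instrument
        ceiling when :func:`puffbox.chamber.apply_instrument` clipped it.
    """

    times: np.ndarray
    grid: SizeGrid
    conc: np.ndarray
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-d")
        if self.conc.shape != (self.times.size, self.grid.n_bins):
            raise ValueError(
                f"conc shape {self.conc.shape} does not match "
                f"(n_times={self.times.size}, n_bins={self.grid.n_bins})"
            )
        diffs = np.diff(self.times)
        if self.times.size >= 2:
            if np.any(diffs <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.saturated is None:
            self.saturated = np.zeros_like(self.conc, dtype=bool)
        else:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if self.saturated.shape != self.conc.shape:
                raise ValueError("saturated mask must match conc shape")

    @property
    def dt_s(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples to define dt_s")
        return float(self.times[1] - self.times[0])

    def total(self) -> np.ndarray:
        """Total number concentration (#/cm^3) summed over bins."""
        return self.conc.sum(axis=1)

    def copy(self) -> "ConcSeries":
        return ConcSeries(
            self.times.copy(), self.grid, self.conc.copy(), self.saturated.copy()
        )

    # -- CSV round-trip -------------------------------------------------

    def to_csv(self, path: str | Path, flags_path: str | Path | None = None) -> None:
        """Write the series; optionally write the saturation sidecar."""
        cols = _bin_columns(self.grid)
        df = pd.DataFrame(self.conc, columns=cols)
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False, float_format="%.17g")
        if flags_path is not None:
            fdf = pd.DataFrame(self.saturated.astype(int), columns=cols)
            fdf.insert(0, "time_s", self.times)
            fdf.to_csv(flags_path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        flags_path: str | Path | None = None,
        instrument_label: str = "composite",
    ) -> "ConcSeries":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("series CSV must have a time_s column")
        grid = _grid_from_columns([c for c in df.columns if c != "time_s"], instrument_label)
        conc = df.drop(columns="time_s").to_numpy(dtype=float)
        saturated = None
        if flags_path is not None and Path(flags_path).exists():
            fdf = pd.read_csv(flags_path)
            saturated = fdf.drop(columns="time_s").to_numpy(dtype=float).astype(bool)
        return cls(df["time_s"].to_numpy(dtype=float), grid, conc, saturated)


def _bin_columns(grid: SizeGrid) -> list[str]:
    e = grid.bin_edges
    return [f"bin_{e[i]:.10g}nm_{e[i + 1]:.10g}nm" for i in range(grid.n_bins)]


def _grid_from_columns(cols: list[str], instrument_label: str) -> SizeGrid:
    edges: list[float] = []
    for i, c in enumerate(cols):
        m = _BIN_RE.match(c)
        if m is None:
            raise ValueError(f"unrecognized bin column name: {c!r}")
        lo, hi = float(m["lo"]), float(m["hi"])
        if i == 0:
            edges.append(lo)
        elif not np.isclose(edges[-1], lo, rtol=1e-6):
            raise ValueError(f"bin columns not contiguous at {c!r}")
        edges.append(hi)
    return SizeGrid(np.array(edges), instrument_label)
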