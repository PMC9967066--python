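"""Size-bin grids for aerosol sizing instruments.

A :class:`SizeGrid` holds the diameter bin edges (nm) of a sizing
instrument channel set.  Bin midpoints are geometric, matching the
log-spaced channels of mobility and optical sizers.  The two instrument
presets mirror a scanning mobility particle sizer (SMPS, 7-300 nm) and an
optical particle sizer (OPS, 0.3-10 um), which together cover the
ultrafine-to-coarse range relevant to e-cigarette aerosol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SMPS_RANGE_NM = (7.0, 300.0)
OPS_RANGE_NM = (300.0, 10_000.0)

_LABELS = ("smps", "ops", "composite")


@dataclass(frozen=True)
class SizeGrid:
    """Diameter bin grid in nm with geometric midpoints.

    Parameters
    ----------
    bin_edges
        Strictly increasing, positive diameters in nm, length ``n + 1``.
    instrument_label
        One of ``smps``, ``ops`` or ``composite``.  The instrument labels
        assert their nominal span (7-300 nm / 300-10000 nm).
    """

    bin_edges: np.ndarray
    instrument_label: str = "composite"
    bin_mids: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-d array of length >= 2")
        if np.any(edges <= 0):
            raise ValueError("bin edges must be positive diameters in nm")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.instrument_label not in _LABELS:
            raise ValueError(f"instrument_label must be one of {_LABELS}")
        if self.instrument_label == "smps":
            _check_span(edges, SMPS_RANGE_NM, "smps")
        elif self.instrument_label == "ops":
            _check_span(edges, OPS_RANGE_NM, "ops")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_mids", np.sqrt(edges[:-1] * edges[1:]))

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def dlog10(self) -> np.ndarray:
        """Per-bin width in decades of diameter, log10(edge_hi/edge_lo)."""
        return np.log10(self.bin_edges[1:] / self.bin_edges[:-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SizeGrid):
            return NotImplemented
        return (
            self.instrument_label == other.instrument_label
            and self.bin_edges.shape == other.bin_edges.shape
            and bool(np.allclose(self.bin_edges, other.bin_edges, rtol=1e-12))
        )


def _check_span(edges: np.ndarray, span: tuple[float, float], label: str) -> None:
    lo, hi = span
    if not (np.isclose(edges[0], lo, rtol=1e-6) and np.isclose(edges[-1], hi, rtol=1e-6)):
        raise ValueError(
            f"{label} grid must span {lo:g}-{hi:g} nm, got {edges[0]:g}-{edges[-1]:g}"
        )


def log_grid(lo_nm: float, hi_nm: float, n_bins: int, label: str = "composite") -> SizeGrid:
    """Logarithmically spaced grid of ``n_bins`` bins between two diameters."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.geomspace(lo_nm, hi_nm, n_bins + 1)
    # pin the endpoints so instrument-span checks see exact bounds
    edges[0], edges[-1] = lo_nm, hi_nm
    return SizeGrid(edges, label)


def default_smps_grid(n_bins: int = 32) -> SizeGrid:
    """SMPS-like grid: log-spaced bins over 7-300 nm (default 32 bins)."""
    return log_grid(*SMPS_RANGE_NM, n_bins, "smps")


def default_ops_grid(n_bins: int = 16) -> SizeGrid:
    """OPS-like grid: log-spaced bins over 0.3-10 um (default 16 bins)."""
    return log_grid(*OPS_RANGE_NM, n_bins, "ops")


def composite_grid(smps: SizeGrid | None = None, ops: SizeGrid | None = None) -> SizeGrid:
    """Concatenate abutting SMPS and OPS grids into one composite grid."""
    smps = smps if smps is not None else default_smps_grid()
    ops = ops if ops is not None else default_ops_grid()
    return SizeGrid(concat_edges(smps, ops), "composite")


def concat_edges(a: SizeGrid, b: SizeGrid) -> np.ndarray:
    """Edges of two abutting grids merged; rejects gaps and overlaps."""
    if not np.isclose(a.bin_edges[-1], b.bin_edges[0], rtol=1e-9):
        raise ValueError(
            "grids must abut: first grid ends at "
            f"{a.bin_edges[-1]:g} nm but second starts at {b.bin_edges[0]:g} nm"
        )
    return np.concatenate([a.bin_edges, b.bin_edges[1:]])
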