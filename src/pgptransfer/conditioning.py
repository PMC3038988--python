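"""Logarithmic activity grids and flow-cytometry histogram conditioning.

Raw list-mode cytometry records (one fluorescence value per event, arbitrary
units on a 1-10^4 log scale) are segregated into logarithmic histograms with a
bin width of 0.05 in log10 units (80 bins at the defaults) and normalized to an
integral area of 1, yielding the probability densities the population model
consumes.  Calcein fluorescence, which is inversely related to P-gp efflux
activity, can be reflected onto the activity axis.

The canonical in-memory basis is probability-per-bin; densities per unit
log10(p) and per unit p are derived views, so "integral area 1.0" is exact by
construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(eq=False)
class ActivityGrid:
    """Logarithmic discretization of the P-gp activity axis p in [1, 10^4].

    Parameters
    ----------
    p_min, p_max
        Endpoints of the instrument's fluorescence scale (arbitrary units).
    bin_width_log10
        Bin width on the log10 axis; the default 0.05 over four decades gives
        80 bins.  The width must tile the span exactly.
    """

    p_min: float = 1.0
    p_max: float = 1.0e4
    bin_width_log10: float = 0.05

    def __post_init__(self) -> None:
        if self.p_min <= 0:
            raise ValueError(f"p_min must be positive, got {self.p_min}")
        if self.p_max <= self.p_min:
            raise ValueError(
                f"p_max must exceed p_min, got p_min={self.p_min}, p_max={self.p_max}"
            )
        if self.bin_width_log10 <= 0:
            raise ValueError(
                f"bin_width_log10 must be positive, got {self.bin_width_log10}"
            )
        span = np.log10(self.p_max) - np.log10(self.p_min)
        n = span / self.bin_width_log10
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"bin_width_log10={self.bin_width_log10} does not tile the "
                f"log10 span [{np.log10(self.p_min)}, {np.log10(self.p_max)}] "
                "into an integer number of bins"
            )

    # the grid is conceptually immutable; identity is the three scalars
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivityGrid):
            return NotImplemented
        return (self.p_min, self.p_max, self.bin_width_log10) == (
            other.p_min,
            other.p_max,
            other.bin_width_log10,
        )

    def __hash__(self) -> int:
        return hash((self.p_min, self.p_max, self.bin_width_log10))

    @cached_property
    def n_bins(self) -> int:
        span = np.log10(self.p_max) - np.log10(self.p_min)
        return int(round(span / self.bin_width_log10))

    @cached_property
    def log_edges(self) -> np.ndarray:
        """Bin boundaries in log10 units, length n_bins + 1."""
        return np.log10(self.p_min) + self.bin_width_log10 * np.arange(
            self.n_bins + 1
        )

    @cached_property
    def edges(self) -> np.ndarray:
        e = 10.0 ** self.log_edges
        # pin the endpoints so boundary events land deterministically
        e[0] = self.p_min
        e[-1] = self.p_max
        return e

    @cached_property
    def log_midpoints(self) -> np.ndarray:
        return 0.5 * (self.log_edges[:-1] + self.log_edges[1:])

    @cached_property
    def midpoints(self) -> np.ndarray:
        """Geometric bin centers on the linear activity axis."""
        return 10.0 ** self.log_midpoints

    @cached_property
    def bin_widths_p(self) -> np.ndarray:
        return np.diff(self.edges)

    def bin_index(self, p: np.ndarray) -> np.ndarray:
        """Bin of each value; bins are [lower, upper) except the last (closed)."""
        idx = np.searchsorted(self.edges, np.asarray(p, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class LogHistogram:
    """Binned logarithmic histogram of list-mode events."""

    grid: ActivityGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts has shape {self.counts.shape}, expected ({self.grid.n_bins},)"
            )
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class DensityState:
    """Normalized cell density over an activity grid plus the count it scales.

    ``bin_prob`` is probability-per-bin and sums to one; ``total_cells`` is the
    population size U(t) the density describes.  ``per_log10`` and ``per_p``
    return the same density per unit log10(p) and per unit p, related by
    u(p) * p * ln(10) = v(log10 p).
    """

    grid: ActivityGrid
    bin_prob: np.ndarray
    total_cells: float = 1.0

    def __post_init__(self) -> None:
        q = np.asarray(self.bin_prob, dtype=float)
        if q.shape != (self.grid.n_bins,):
            raise ValueError(
                f"bin_prob has shape {q.shape}, expected ({self.grid.n_bins},)"
            )
        if np.any(q < -1e-12):
            raise ValueError("bin_prob has negative entries")
        q = np.maximum(q, 0.0)
        s = q.sum()
        if abs(s - 1.0) > 1e-8:
            raise ValueError(f"bin_prob sums to {s!r}, not 1 (unnormalized density)")
        self.bin_prob = q / s
        if self.total_cells < 0:
            raise ValueError("total_cells must be nonnegative")

    def per_log10(self) -> np.ndarray:
        """Density of probability per unit log10(p)."""
        return self.bin_prob / self.grid.bin_width_log10

    def per_p(self) -> np.ndarray:
        """Density of probability per unit p."""
        return self.bin_prob / self.grid.bin_widths_p

    def mean_activity(self) -> float:
        """Mean activity (midpoint quadrature on the grid)."""
        return float(self.bin_prob @ self.grid.midpoints)

    def mass_below(self, p_star: float) -> float:
        """Probability mass at p < p_star; the containing bin is split by the
        fraction of its log-width lying below p_star."""
        frac = np.clip(
            (np.log10(p_star) - self.grid.log_edges[:-1]) / self.grid.bin_width_log10,
            0.0,
            1.0,
        )
        return float(self.bin_prob @ frac)


def bin_events(events, grid: ActivityGrid) -> LogHistogram:
    """Bin list-mode events into a logarithmic histogram.

    Values outside [p_min, p_max] are clipped to the instrument rails before
    binning; the clipped count is logged.
    """
    values = np.asarray(getattr(events, "values", events), dtype=float)
    if values.size == 0:
        raise ValueError("cannot bin an empty event list")
    n_clipped = int(np.sum((values < grid.p_min) | (values > grid.p_max)))
    if n_clipped:
        log.info("clipped %d of %d events to [%g, %g]",
                 n_clipped, values.size, grid.p_min, grid.p_max)
        values = np.clip(values, grid.p_min, grid.p_max)
    counts = np.bincount(grid.bin_index(values), minlength=grid.n_bins)
    return LogHistogram(grid, counts)


def normalize_density(hist: LogHistogram) -> DensityState:
    """Scale a histogram to an integral area of 1 (a density of probability)."""
    if hist.n_total < 1:
        raise ValueError("cannot normalize an all-zero histogram")
    return DensityState(hist.grid, hist.counts / hist.n_total,
                        total_cells=float(hist.n_total))


def activity_from_calcein(fluorescence, mapping_constant: float = 4.0):
    """Map calcein fluorescence to efflux activity by reflecting the log axis.

    Calcein accumulation is an inverse function of P-gp activity, so
    p = 10^(mapping_constant - log10 fluorescence).  The default constant 4
    reflects the full 1-10^4 scale and makes the map an involution.
    """
    f = np.asarray(fluorescence, dtype=float)
    if np.any(f < 1.0 - 1e-9) or np.any(f > 1.0e4 + 1e-6):
        raise ValueError("fluorescence outside the instrument range [1, 1e4]")
    p = 10.0 ** (mapping_constant - np.log10(f))
    return float(p) if np.isscalar(fluorescence) else p


_HIST_COLUMNS = ["bin_lower", "bin_upper", "count"]
_DENS_COLUMNS = ["bin_lower", "bin_upper", "probability"]


def write_histogram(hist: LogHistogram, path) -> None:
    pd.DataFrame(
        {
            "bin_lower": hist.grid.edges[:-1],
            "bin_upper": hist.grid.edges[1:],
            "count": hist.counts.astype(int),
        }
    ).to_csv(path, index=False)


def _read_table(path, columns):
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required header column(s) {missing}; "
            f"expected columns {columns}"
        )
    return df


def _grid_from_edges(path, lower, upper, grid: ActivityGrid | None) -> ActivityGrid:
    edges = np.append(lower, upper[-1])
    if np.any(np.diff(edges) <= 0):
        raise ValueError(f"{path}: bin edges are not strictly increasing")
    if not np.allclose(lower[1:], upper[:-1], rtol=1e-9):
        raise ValueError(f"{path}: bin_upper does not chain onto the next bin_lower")
    widths = np.diff(np.log10(edges))
    if not np.allclose(widths, widths[0], rtol=1e-6):
        raise ValueError(f"{path}: bins are not uniform on the log10 axis")
    inferred = ActivityGrid(float(edges[0]), float(edges[-1]), float(widths[0]))
    if grid is not None:
        if inferred.n_bins != grid.n_bins or not np.allclose(
            inferred.edges, grid.edges, rtol=1e-9
        ):
            raise ValueError(f"{path}: bin edges mismatch the declared grid")
        return grid
    return inferred


def read_histogram(path, grid: ActivityGrid | None = None) -> LogHistogram:
    """Read a histogram from delimited text (columns bin_lower, bin_upper, count).

    ``write_histogram`` then ``read_histogram`` is the identity.  If ``grid``
    is given the file's edges must match it.
    """
    df = _read_table(path, _HIST_COLUMNS)
    bad = np.flatnonzero(df["count"].to_numpy() < 0)
    if bad.size:
        raise ValueError(f"{path}: negative count at data row {bad[0] + 1}")
    g = _grid_from_edges(path, df["bin_lower"].to_numpy(), df["bin_upper"].to_numpy(),
                         grid)
    return LogHistogram(g, df["count"].to_numpy().astype(int))


def write_density(density: DensityState, path) -> None:
    pd.DataFrame(
        {
            "bin_lower": density.grid.edges[:-1],
            "bin_upper": density.grid.edges[1:],
            "probability": density.bin_prob,
        }
    ).to_csv(path, index=False)


def read_density(path, grid: ActivityGrid | None = None,
                 total_cells: float = 1.0) -> DensityState:
    df = _read_table(path, _DENS_COLUMNS)
    prob = df["probability"].to_numpy(dtype=float)
    bad = np.flatnonzero(prob < 0)
    if bad.size:
        raise ValueError(f"{path}: negative probability at data row {bad[0] + 1}")
    g = _grid_from_edges(path, df["bin_lower"].to_numpy(), df["bin_upper"].to_numpy(),
                         grid)
    return DensityState(g, prob, total_cells=total_cells)
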