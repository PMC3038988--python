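"""Synthetic flow-cytometry list-mode data with the study's statistical structure.

No cytometry accession accompanies the co-culture experiments, so this module
emulates their inputs: ~10,000-event samples, day-0 50:50 bimodal mixtures of
low-activity (sensitive) and high-activity (resistant) subpopulations, and
forward-simulated "observed" samples drawn from a known density for
parameter-recovery experiments.

Peaks are modeled as Gaussian components on the log10 fluorescence axis
(log-normal in fluorescence), the shape cytometry histograms show on a log
scale.  Draws falling outside the 1-10^4 instrument range are clipped to the
rails, mimicking saturation; the clipped fraction is logged.  The default
day-0 template puts the sensitive peak at 10^0.75 and the resistant peak at
10^2.5 with sd 0.2 log10 units — well-separated peaks with the whole dynamic
range available for transfer.  The peak widths are plausible, not fitted: the
source experiments report peak positions only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .conditioning import ActivityGrid, DensityState

log = logging.getLogger(__name__)

DEFAULT_SEED = 12345
AXES = ("activity", "calcein", "pgp")

#: Default day-0 co-culture template peaks (log10 fluorescence units).
SENSITIVE_MEDIAN_LOG10 = 0.75
RESISTANT_MEDIAN_LOG10 = 2.5
PEAK_SD_LOG10 = 0.2


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    median_log10: float
    sd_log10: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"component weight must be nonnegative, got {self.weight}")
        if self.sd_log10 < 0:
            raise ValueError(f"sd_log10 must be nonnegative, got {self.sd_log10}")


@dataclass(frozen=True)
class MixtureSpec:
    """Mixture of log-normal peaks on one cytometry axis; weights sum to 1."""

    components: tuple
    axis: str = "activity"

    def __post_init__(self) -> None:
        comps = tuple(
            c if isinstance(c, MixtureComponent) else MixtureComponent(*c)
            for c in self.components
        )
        object.__setattr__(self, "components", comps)
        if len(comps) == 0:
            raise ValueError("components must not be empty")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, expected 1")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")

    @classmethod
    def fifty_fifty(
        cls,
        median_log10_a: float = SENSITIVE_MEDIAN_LOG10,
        median_log10_b: float = RESISTANT_MEDIAN_LOG10,
        sd_log10: float = PEAK_SD_LOG10,
        axis: str = "activity",
    ) -> "MixtureSpec":
        """The day-0 50:50 sensitive:resistant seeding mixture."""
        return cls(
            components=(
                MixtureComponent(0.5, median_log10_a, sd_log10),
                MixtureComponent(0.5, median_log10_b, sd_log10),
            ),
            axis=axis,
        )


@dataclass
class EventSample:
    """List-mode events: one fluorescence reading per cell, in [1, 1e4]."""

    values: np.ndarray
    channel_label: str = "activity"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 1.0) or np.any(self.values > 1.0e4):
            raise ValueError("event values must lie in [1, 1e4] after clipping")

    @property
    def n(self) -> int:
        return len(self.values)


def generate_mixture_events(
    spec: MixtureSpec, n: int, seed: int = DEFAULT_SEED
) -> EventSample:
    """Draw n events component-wise: log10(value) ~ Normal(median, sd), then
    clip to the instrument range.  Identical seeds give identical samples."""
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in spec.components])
    medians = np.array([c.median_log10 for c in spec.components])
    sds = np.array([c.sd_log10 for c in spec.components])
    which = rng.choice(len(weights), size=n, p=weights)
    x = rng.normal(medians[which], sds[which])
    values = 10.0 ** x
    n_clip = int(np.sum((values < 1.0) | (values > 1.0e4)))
    if n_clip:
        log.info("clipped %d/%d events to the [1, 1e4] rails", n_clip, n)
    values = np.clip(values, 1.0, 1.0e4)
    return EventSample(values, channel_label=spec.axis, seed=seed)


def _lognormal_bin_probs(
    grid: ActivityGrid, median_log10: float, sd_log10: float
) -> np.ndarray:
    """Exact per-bin probabilities of one log-normal bump, renormalized to the
    grid support (truncation mass is negligible for in-range peaks)."""
    if sd_log10 == 0:
        probs = np.zeros(grid.n_bins)
        probs[grid.bin_index(10.0 ** median_log10)] = 1.0
        return probs
    cdf = norm.cdf(grid.log_edges, loc=median_log10, scale=sd_log10)
    probs = np.diff(cdf)
    return probs / probs.sum()


def lognormal_template(
    median_log10: float, sd_log10: float = PEAK_SD_LOG10,
    grid: ActivityGrid | None = None,
) -> DensityState:
    """Single-peak density template (e.g. a pure sensitive or resistant line)."""
    grid = grid or ActivityGrid()
    return DensityState(grid, _lognormal_bin_probs(grid, median_log10, sd_log10))


def day0_coculture_template(
    sensitive_median_log10: float = SENSITIVE_MEDIAN_LOG10,
    resistant_median_log10: float = RESISTANT_MEDIAN_LOG10,
    sd_log10: float = PEAK_SD_LOG10,
    resistant_fraction: float = 0.5,
    grid: ActivityGrid | None = None,
) -> DensityState:
    """Discretized day-0 activity density: a two-peak mixture of log-normal
    bumps, normalized to integral 1 on the grid (the conditioned day-0
    distribution the model takes as input)."""
    grid = grid or ActivityGrid()
    for name, m in (
        ("sensitive_median_log10", sensitive_median_log10),
        ("resistant_median_log10", resistant_median_log10),
    ):
        if not 0.0 <= m <= 4.0:
            raise ValueError(f"{name} must lie in [0, 4], got {m}")
    if not 0.0 <= resistant_fraction <= 1.0:
        raise ValueError(
            f"resistant_fraction must lie in [0, 1], got {resistant_fraction}"
        )
    probs = (1.0 - resistant_fraction) * _lognormal_bin_probs(
        grid, sensitive_median_log10, sd_log10
    ) + resistant_fraction * _lognormal_bin_probs(
        grid, resistant_median_log10, sd_log10
    )
    return DensityState(grid, probs / probs.sum())


def forward_observe(
    density: DensityState, n: int, seed: int = DEFAULT_SEED
) -> EventSample:
    """Sample n events from a density: bin-wise multinomial counts, positions
    uniform inside each bin in log10 units, order shuffled.  Reproducible
    under the seed."""
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    rng = np.random.default_rng(seed)
    grid = density.grid
    counts = rng.multinomial(n, density.bin_prob)
    lowers = np.repeat(grid.log_edges[:-1], counts)
    x = lowers + grid.bin_width_log10 * rng.random(n)
    values = 10.0 ** x[rng.permutation(n)]
    return EventSample(values, channel_label="activity", seed=seed)


def write_events(sample: EventSample, path) -> None:
    """Write events as 2-column delimited text (event_id, fluorescence)."""
    pd.DataFrame(
        {"event_id": np.arange(sample.n), "fluorescence": sample.values}
    ).to_csv(path, index=False)


def read_events(path, channel_label: str = "activity") -> EventSample:
    df = pd.read_csv(path)
    for col in ("event_id", "fluorescence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required header column {col!r}")
    values = df["fluorescence"].to_numpy(dtype=float)
    n_clip = int(np.sum((values < 1.0) | (values > 1.0e4)))
    if n_clip:
        log.info("%s: clipped %d/%d events to the [1, 1e4] rails",
                 path, n_clip, len(values))
        values = np.clip(values, 1.0, 1.0e4)
    return EventSample(values, channel_label=channel_label)
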