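"""Chemotherapy-cycle simulation on mixed sensitive/resistant inocula.

The treatment is an idealized square wave: a 1 uM doxorubicin bolus reaching
the extracellular compartment with no delay, held for ``days_on`` days, then
interrupted for ``days_off`` days, cycled ``n_cycles`` times (defaults:
10 on / 4 off, 4 cycles, 56 days).  Pharmacokinetics are deliberately
excluded.  Inocula default to 1e4 cells with a small resistant fraction
(0.1% = 10 cells or 1% = 100 cells), mixed from single-peak sensitive and
resistant density templates.  Sensitive/resistant counting always classifies
against the fixed 1 uM reference, whatever the instantaneous concentration.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .conditioning import ActivityGrid, DensityState
from .dynamics import GrowthModel, ModelState, Trajectory, integrate
from .synthetic import (
    PEAK_SD_LOG10,
    RESISTANT_MEDIAN_LOG10,
    SENSITIVE_MEDIAN_LOG10,
    lognormal_template,
)
from .transfer import TransferParams


@dataclass(frozen=True)
class TreatmentSchedule:
    """Piecewise-constant drug concentration c(t) over cycled regimens."""

    dose: float = 1.0
    days_on: float = 10.0
    days_off: float = 4.0
    n_cycles: int = 4

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be nonnegative, got {self.dose}")
        for name in ("days_on", "days_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.n_cycles < 0:
            raise ValueError(f"n_cycles must be nonnegative, got {self.n_cycles}")

    @property
    def period(self) -> float:
        return self.days_on + self.days_off

    @property
    def total_days(self) -> float:
        return self.n_cycles * self.period


def concentration_at(t, schedule: TreatmentSchedule):
    """Drug concentration at time t (days): ``dose`` while (t mod period) <
    days_on within the treated window, else 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    if schedule.period == 0 or schedule.n_cycles == 0:
        out = np.zeros_like(t_arr)
    else:
        out = np.where(
            (np.mod(t_arr, schedule.period) < schedule.days_on)
            & (t_arr < schedule.total_days),
            schedule.dose,
            0.0,
        )
    return float(out) if np.isscalar(t) else out


def next_discontinuity(t: float, schedule: TreatmentSchedule) -> float:
    """Earliest schedule switch time strictly after t (inf when none remain)."""
    if schedule.period == 0 or schedule.n_cycles == 0 or t >= schedule.total_days:
        return np.inf
    k, r = divmod(t, schedule.period)
    nxt = k * schedule.period + (
        schedule.days_on if r < schedule.days_on else schedule.period
    )
    return float(min(nxt, schedule.total_days))


@dataclass
class InoculumSpec:
    """Initial mixed population: total size, resistant fraction, and the
    normalized density templates of each subpopulation."""

    total_cells: float = 1.0e4
    resistant_fraction: float = 0.001
    sensitive_template: DensityState | None = None
    resistant_template: DensityState | None = None

    def __post_init__(self) -> None:
        if self.total_cells < 0:
            raise ValueError("total_cells must be nonnegative")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ValueError(
                f"resistant_fraction must lie in [0, 1], got {self.resistant_fraction}"
            )


def default_templates(
    grid: ActivityGrid | None = None,
    sensitive_median_log10: float = SENSITIVE_MEDIAN_LOG10,
    resistant_median_log10: float = RESISTANT_MEDIAN_LOG10,
    sd_log10: float = PEAK_SD_LOG10,
) -> tuple[DensityState, DensityState]:
    """Single-peak sensitive and resistant templates at the day-0 defaults."""
    grid = grid or ActivityGrid()
    return (
        lognormal_template(sensitive_median_log10, sd_log10, grid),
        lognormal_template(resistant_median_log10, sd_log10, grid),
    )


def build_inoculum(spec: InoculumSpec, grid: ActivityGrid | None = None) -> ModelState:
    """Mix the templates: density = (1 - fraction) sensitive + fraction
    resistant, scaled to the inoculum size."""
    grid = grid or ActivityGrid()
    sens, res = spec.sensitive_template, spec.resistant_template
    if sens is None or res is None:
        d_sens, d_res = default_templates(grid)
        sens = sens or d_sens
        res = res or d_res
    if sens.grid != res.grid:
        raise ValueError("sensitive and resistant templates use different grids")
    if sens.grid != grid:
        raise ValueError("templates do not match the requested grid")
    mix = (1.0 - spec.resistant_fraction) * sens.bin_prob \
        + spec.resistant_fraction * res.bin_prob
    return ModelState(
        t=0.0,
        density=DensityState(grid, mix),
        total_cells=float(spec.total_cells),
    )


def simulate_regimen(
    spec: InoculumSpec,
    schedule: TreatmentSchedule,
    params: TransferParams,
    gm: GrowthModel,
    transfers_enabled: bool = True,
    dt: float = 0.01,
    grid: ActivityGrid | None = None,
    snapshot_every: float | None = None,
) -> Trajectory:
    """Run the full cycled regimen; with transfers disabled tau is forced to 0
    so only the growth law acts (the transfer-abolished control)."""
    if spec.sensitive_template is not None:
        grid = grid or spec.sensitive_template.grid
    grid = grid or ActivityGrid()
    state0 = build_inoculum(spec, grid)
    p = params if transfers_enabled else replace(params, tau=0.0)
    return integrate(
        state0,
        t_end=schedule.total_days,
        params=p,
        gm=gm,
        schedule=schedule,
        dt=dt,
        snapshot_every=snapshot_every,
    )
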