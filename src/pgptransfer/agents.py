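"""Event-driven individual-cell simulation of the transfer rules, with growth.

This is the stochastic counterpart of the continuum model, used as a
brute-force oracle.  Each cell carries an exponential clock of rate tau (mean
inter-initiation time 1/tau, 2.5 days at the fitted rate); when a clock fires
the initiator is paired with a partner drawn uniformly from the rest of the
ensemble and the pair rule is applied.  The ensemble event rate is therefore
N * tau, and each cell *experiences* events at rate 2 tau — once through its
own clock and once through being chosen as a partner — which is exactly the
factor 2 tau multiplying (T - u) in the continuum equation.  The net growth
rate rho is split minimally
into a birth rate max(rho, 0) and a death rate max(-rho, 0); daughters inherit
the parent's activity and deaths remove cells instantly.  Time advances by
exact exponential waiting times, with rates refreshed after every event and at
treatment-schedule discontinuities.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

from .dynamics import GrowthModel, ModelState
from .conditioning import DensityState
from .therapy import TreatmentSchedule, concentration_at, next_discontinuity
from .transfer import TransferParams, transfer_pair


@dataclass
class CellEnsemble:
    """Per-cell activity values plus event counters.

    ``transfers`` counts pairing events (rule-A2 clock ticks); ``exchanges``
    counts the subset in which activity actually moved (difference inside the
    admissible window).
    """

    activities: np.ndarray
    t: float = 0.0
    seed: int | None = None
    transfers: int = 0
    exchanges: int = 0
    births: int = 0
    deaths: int = 0
    extinct: bool = False

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.size and (
            self.activities.min() < 1.0 or self.activities.max() > 1.0e4
        ):
            raise ValueError("cell activities must lie in [1, 1e4]")

    @property
    def n(self) -> int:
        return len(self.activities)


def sample_ensemble(n: int, density: DensityState, seed: int | None = 12345,
                    rng: np.random.Generator | None = None) -> CellEnsemble:
    """Draw n cells from a density (bin-wise counts, uniform-in-log positions)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    grid = density.grid
    counts = rng.multinomial(n, density.bin_prob)
    x = np.repeat(grid.log_edges[:-1], counts) + grid.bin_width_log10 * rng.random(n)
    return CellEnsemble(10.0 ** x[rng.permutation(n)], seed=seed)


def observed_transfer_interval(ensemble: CellEnsemble) -> float:
    """Mean per-cell time between initiated transfer events in a constant-N
    run: every event has one initiating clock among the N cells, so the
    per-cell initiation rate is transfers / (N * t) and the mean interval its
    inverse (1/tau in expectation)."""
    if ensemble.transfers == 0:
        return np.inf
    return ensemble.n * ensemble.t / ensemble.transfers


def simulate_agents(
    initial,
    params: TransferParams,
    gm: GrowthModel | None = None,
    schedule: TreatmentSchedule | None = None,
    t_end: float = 6.0,
    seed: int = 12345,
    snapshot_times=None,
) -> list[CellEnsemble]:
    """Exact-time stochastic simulation from ``initial`` (a CellEnsemble, or a
    (n0, DensityState) pair sampled under the same seed) up to t_end.

    Returns ensemble snapshots at ``snapshot_times`` (default: t_end only).
    Extinction terminates the run with a final snapshot flagged ``extinct``.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    rng = np.random.default_rng(seed)
    if isinstance(initial, CellEnsemble):
        acts = initial.activities.copy()
        counters = dict(
            transfers=initial.transfers,
            exchanges=initial.exchanges,
            births=initial.births,
            deaths=initial.deaths,
        )
        t0 = initial.t
    else:
        n0, density = initial
        acts = sample_ensemble(int(n0), density, rng=rng).activities
        counters = dict(transfers=0, exchanges=0, births=0, deaths=0)
        t0 = 0.0

    snaps_due = sorted(snapshot_times) if snapshot_times is not None else [t_end]
    snaps_due = [s for s in snaps_due if s > t0]
    snapshots: list[CellEnsemble] = []

    # dynamic array with amortized growth; n is the live count
    cap = max(len(acts) * 2, 16)
    buf = np.empty(cap)
    n = len(acts)
    buf[:n] = acts
    t = t0

    def snapshot(at: float, extinct: bool = False) -> None:
        snapshots.append(
            CellEnsemble(buf[:n].copy(), t=at, seed=seed, extinct=extinct, **counters)
        )

    def birth_death_rates(c: float):
        """(b_vec, d_vec, B, D); vectors are None when rates are uniform."""
        if gm is None:
            return None, None, 0.0, 0.0
        rho = gm.rate(buf[:n], c)
        b = np.maximum(rho, 0.0)
        d = np.maximum(-rho, 0.0)
        uniform = np.ptp(rho) < 1e-15
        return (None if uniform else b), (None if uniform else d), b.sum(), d.sum()

    while t < t_end:
        if n == 0:
            snapshot(t, extinct=True)
            return snapshots
        c = concentration_at(t, schedule) if schedule is not None else 0.0
        seg_end = min(
            t_end,
            next_discontinuity(t, schedule) if schedule is not None else np.inf,
        )
        b_vec, d_vec, b_tot, d_tot = birth_death_rates(c)
        transfer_rate = n * params.tau if n >= 2 else 0.0
        total_rate = transfer_rate + b_tot + d_tot
        if total_rate == 0.0:
            while snaps_due and snaps_due[0] <= seg_end:
                snapshot(snaps_due.pop(0))
            t = seg_end
            continue
        dt = rng.exponential(1.0 / total_rate)
        t_next = t + dt
        while snaps_due and snaps_due[0] <= min(t_next, seg_end):
            snapshot(snaps_due.pop(0))
        if t_next > seg_end:
            t = seg_end
            continue
        t = t_next
        u = rng.uniform(0.0, total_rate)
        if u < transfer_rate:
            i = int(rng.integers(n))
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
            counters["transfers"] += 1
            p1, p2 = buf[i], buf[j]
            q1, q2 = transfer_pair(p1, p2, params)
            if (q1, q2) != (p1, p2):
                counters["exchanges"] += 1
                buf[i], buf[j] = q1, q2
        elif u < transfer_rate + b_tot:
            if b_vec is None:
                i = int(rng.integers(n))
            else:
                i = int(rng.choice(n, p=b_vec / b_tot))
            if n == cap:
                cap *= 2
                grown = np.empty(cap)
                grown[:n] = buf[:n]
                buf = grown
            buf[n] = buf[i]  # daughter inherits the parent's activity
            n += 1
            counters["births"] += 1
        else:
            if d_vec is None:
                i = int(rng.integers(n))
            else:
                i = int(rng.choice(n, p=d_vec / d_tot))
            buf[i] = buf[n - 1]
            n -= 1
            counters["deaths"] += 1

    while snaps_due:
        snapshot(snaps_due.pop(0))
    if not snapshots or snapshots[-1].t < t_end:
        snapshot(t_end)
    return snapshots


def compare_to_pde(ensemble: CellEnsemble, state: ModelState) -> float:
    """Wasserstein-1 distance on the log10 activity axis between the
    ensemble's empirical distribution and the model density (bin masses
    placed at log midpoints)."""
    if ensemble.n == 0:
        raise ValueError("cannot compare an empty ensemble")
    grid = state.density.grid
    return float(
        wasserstein_distance(
            np.log10(ensemble.activities),
            grid.log_midpoints,
            v_weights=state.density.bin_prob,
        )
    )
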