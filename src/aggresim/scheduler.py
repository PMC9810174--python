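"""Multi-timescale integration: diffusion to pseudo-steady state, biology
on the slow step, division/shoving on the slowest.

One outer step is:

1. solve all substrate fields to pseudo-steady state (residual rule);
2. advance every active cell's mass by dt_bac with its local growth rate,
   then apply inactivation/reactivation;
3. at division-check boundaries: process divisions, run the shoving pass,
   apply optional detachment, and relabel the grid zones;
4. update the bulk boundary condition (fixed Dirichlet by default, or an
   optional well-mixed reactor balance).

dt_bac adapts to the average microbial activity: no active cell changes
its mass by more than ``growth_eps`` (default 5%) per step, capped at
``dt_bac_max``.  Runs are bit-reproducible for a given configuration and
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    CellState,
    ConfigurationError,
    EcologyPreset,
    IntegrityError,
    SimulationConfig,
    generate_inoculum,
)
from . import cell_dynamics as cd
from . import mechanics as mech
from .reaction_diffusion import (
    ConcentrationField,
    GridSpec,
    PoissonOperator,
    SolverSettings,
    boundary_flux_balance,
    assemble_reaction_term,
    compute_growth_rates,
    solve_pseudo_steady,
)

__all__ = [
    "SchedulerSettings",
    "AggregateSnapshot",
    "Trajectory",
    "SteadyStateResult",
    "run_simulation",
    "detect_steady_state",
]

log = logging.getLogger(__name__)


@dataclass
class SchedulerSettings:
    """Timescale and convergence controls of the outer loop."""

    dt_bac_max: float = 0.5  # h, cap on the biology step
    growth_eps: float = 0.05  # max fractional mass change per step
    dt_div_every: int = 1  # division/shoving check every N outer steps
    solver: SolverSettings = field(default_factory=SolverSettings)
    steady_window: float = 10.0  # h
    steady_tol: float = 0.05  # relative fraction
    bulk_mode: str = "dirichlet"  # or "reactor"
    reactor_volume_l: float = 1e-9

    def __post_init__(self) -> None:
        if self.dt_bac_max <= 0 or self.growth_eps <= 0:
            raise ConfigurationError("dt_bac_max and growth_eps must be > 0")
        if self.bulk_mode not in ("dirichlet", "reactor"):
            raise ConfigurationError("bulk_mode must be 'dirichlet' or 'reactor'")


@dataclass
class AggregateSnapshot:
    """Time-stamped state: cells, bulk values and per-population summary."""

    time: float
    cells: CellState
    bulk: dict[str, float]
    centre: tuple[float, float]
    radius: float
    summary: dict[str, float]
    fields: ConcentrationField | None = None


@dataclass
class SteadyStateResult:
    steady: bool
    time: float | None
    indeterminate: bool = False


class Trajectory:
    """Ordered snapshots of one run plus scalar per-snapshot summaries."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.snapshots: list[AggregateSnapshot] = []
        self.steady_time: float | None = None
        self.stop_reason: str = "end_time"
        self.dt_history: list[float] = []

    def append(self, snap: AggregateSnapshot) -> None:
        if self.snapshots and snap.time <= self.snapshots[-1].time:
            raise ValueError("snapshot timestamps must be strictly increasing")
        self.snapshots.append(snap)

    @property
    def final(self) -> AggregateSnapshot:
        return self.snapshots[-1]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.summary for s in self.snapshots])


def _snapshot_summary(
    state: CellState, ecology: EcologyPreset, bulk: dict, time: float, radius: float
) -> dict[str, float]:
    pops = state.populations
    row: dict[str, float] = {"time_h": time, "n_cells": state.n, "radius_um": radius}
    n_active_total = int(state.active.sum())
    for i, name in enumerate(pops):
        sel = state.pop == i
        act = sel & state.active
        row[f"count_{name}"] = int(sel.sum())
        row[f"count_active_{name}"] = int(act.sum())
        row[f"abundance_{name}"] = sel.sum() / state.n if state.n else np.nan
        row[f"abundance_active_{name}"] = (
            act.sum() / n_active_total if n_active_total else np.nan
        )
        row[f"median_mu_{name}"] = (
            float(np.median(state.mu[act])) if act.any() else np.nan
        )
    row["total_mass_mol"] = float(state.mass.sum())
    for s, v in bulk.items():
        row[f"bulk_{s}"] = v
    return row


# --- steady-state detection -------------------------------------------------


def _window_stable(values: np.ndarray, tol: float, floor: float) -> bool:
    finite = np.isfinite(values)
    if not finite.any():
        return True  # metric undefined throughout the window (e.g. extinct)
    if not finite.all():
        return False
    v = values[finite]
    scale = max(abs(float(np.mean(v))), floor)
    return float(v.max() - v.min()) <= tol * scale


def detect_steady_state(
    trajectory: Trajectory,
    window: float | None = None,
    tol: float | None = None,
) -> SteadyStateResult:
    """First time at which active abundances, bulk concentrations and
    per-population median growth rates all stay within ``tol`` (relative)
    over a trailing window.
    """
    cfg = trajectory.config
    window = cfg.scheduler.steady_window if window is None else window
    tol = cfg.scheduler.steady_tol if tol is None else tol
    snaps = trajectory.snapshots
    if len(snaps) < 2 or snaps[-1].time - snaps[0].time < window:
        return SteadyStateResult(False, None, indeterminate=True)

    df = trajectory.summary_frame()
    times = df["time_h"].to_numpy()
    pops = snaps[0].cells.populations
    metrics: list[tuple[str, float]] = []
    for name in pops:
        metrics.append((f"abundance_active_{name}", 0.02))
        metrics.append((f"median_mu_{name}", 1e-3))
    for s in snaps[0].bulk:
        metrics.append((f"bulk_{s}", 1e-9))

    for k in range(len(snaps)):
        t_k = times[k]
        if t_k - times[0] < window:
            continue
        in_win = (times >= t_k - window) & (times <= t_k)
        if in_win.sum() < 2:
            continue
        if all(
            _window_stable(df.loc[in_win, m].to_numpy(), tol, floor)
            for m, floor in metrics
        ):
            return SteadyStateResult(True, float(t_k))
    return SteadyStateResult(False, None)


# --- the main loop ----------------------------------------------------------


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one seeded experiment from inoculum to end time.

    Stops early when steady state is detected (``stop_at_steady``) or when
    the aggregate reaches ``stop_radius``; raises on solver failure or if
    the aggregate outgrows the grid.
    """
    ecology: EcologyPreset = config.ecology
    grid: GridSpec = config.grid
    sched: SchedulerSettings = config.scheduler
    shoving = config.shoving or mech.ShovingSettings()

    seedseq = np.random.SeedSequence(config.seed)
    inoc_seed, engine_seed = seedseq.spawn(2)
    rng = np.random.default_rng(engine_seed)

    cells = (
        []
        if config.n_cells == 0
        else generate_inoculum(
            config, seed=int(inoc_seed.generate_state(1)[0] % (2**31))
        )
    )
    state = CellState.from_cells(cells, tuple(p.name for p in ecology.populations))
    next_id = int(state.ids.max()) + 1 if state.n else 0
    m_min_by_pop = np.array([p.M_min for p in ecology.populations])
    diffusivities = {s.name: s.diffusion_coefficient for s in ecology.substrates}

    fields = ConcentrationField.from_ecology(ecology, grid)
    traj = Trajectory(config)

    operator: PoissonOperator | None = None
    zone_key: tuple | None = None

    def refresh_operator() -> None:
        nonlocal operator, zone_key
        if state.n == 0:
            centre, radius = (0.0, 0.0), 0.0
        else:
            centre, radius = mech.aggregate_centre_and_radius(state, ecology)
        cq = (round(centre[0] / grid.h), round(centre[1] / grid.h))
        rq = math.ceil(radius / grid.h) + 1
        key = (cq, rq)
        if key != zone_key:
            zones = grid.label_zones(
                (cq[0] * grid.h, cq[1] * grid.h), rq * grid.h
            )
            operator = PoissonOperator(grid, zones)
            zone_key = key

    refresh_operator()

    t = 0.0
    next_snap = 0.0
    step = 0
    while True:
        fields, report = solve_pseudo_steady(
            fields, state, ecology, grid, sched.solver, operator=operator
        )
        if state.n:
            mu = compute_growth_rates(state, fields, ecology, grid)
            state.mu = np.where(state.active, mu, 0.0)
            centre, radius = mech.aggregate_centre_and_radius(state, ecology)
        else:
            mu = np.empty(0)
            centre, radius = (0.0, 0.0), 0.0

        if t >= next_snap - 1e-9:
            if log.isEnabledFor(logging.INFO):
                log.info(
                    "t=%.2f h: n=%d cells (%d active), radius=%.1f um, "
                    "solver %d iterations, worst residual %.2e",
                    t, state.n, int(state.active.sum()), radius,
                    report.iterations, report.worst(),
                )
            snap = AggregateSnapshot(
                time=t,
                cells=state.copy(),
                bulk=dict(fields.bulk),
                centre=centre,
                radius=radius,
                summary=_snapshot_summary(state, ecology, fields.bulk, t, radius),
                fields=fields.copy() if config.store_fields else None,
            )
            traj.append(snap)
            next_snap += config.snapshot_interval
            if config.stop_at_steady:
                res = detect_steady_state(traj)
                if res.steady:
                    traj.steady_time = res.time
                    traj.stop_reason = "steady_state"
                    break
        if config.stop_radius is not None and radius >= config.stop_radius:
            traj.stop_reason = "stop_radius"
            break

        if t >= config.end_time - 1e-9:
            break

        # --- adaptive biology step
        active_mu = np.abs(mu[state.active]) if state.n else np.empty(0)
        peak = float(active_mu.max()) if active_mu.size else 0.0
        dt = sched.dt_bac_max if peak == 0.0 else min(
            sched.dt_bac_max, sched.growth_eps / peak
        )
        dt = min(dt, config.end_time - t, next_snap - t)
        if dt <= 0:
            dt = min(sched.dt_bac_max, config.end_time - t)

        if state.n:
            cd.advance_masses(state, mu, dt)
            cd.apply_activity_rules(state, mu, m_min_by_pop)
        t += dt
        step += 1
        traj.dt_history.append(dt)

        if state.n and step % sched.dt_div_every == 0:
            state, events, next_id = cd.perform_divisions(
                state, rng, list(ecology.populations), next_id
            )
            if state.n > 1:
                mech.resolve_overlaps(state, ecology, shoving)
            if config.detachment_radius is not None:
                state = mech.apply_detachment(state, config.detachment_radius)
            try:
                refresh_operator()
            except IntegrityError:
                # a configured radius guard means the run ends gracefully
                # when shoving pushes the rim past the label limit mid-step
                if config.stop_radius is None:
                    raise
                traj.stop_reason = "stop_radius"
                break

        if sched.bulk_mode == "reactor":
            reaction = assemble_reaction_term(state, fields, ecology, grid)
            balance = boundary_flux_balance(
                fields, reaction, grid, operator.zones, diffusivities
            )
            for s in fields.substrate_names:
                influx = balance[s]["influx_mol_per_h"]
                new_bulk = fields.bulk[s] - dt * influx / sched.reactor_volume_l
                fields.set_bulk(s, max(new_bulk, 0.0))

    # final snapshot if the loop ended between snapshot times
    if traj.snapshots and traj.snapshots[-1].time < t - 1e-9:
        centre, radius = (
            mech.aggregate_centre_and_radius(state, ecology)
            if state.n
            else ((0.0, 0.0), 0.0)
        )
        traj.append(
            AggregateSnapshot(
                time=t,
                cells=state.copy(),
                bulk=dict(fields.bulk),
                centre=centre,
                radius=radius,
                summary=_snapshot_summary(state, ecology, fields.bulk, t, radius),
                fields=fields.copy() if config.store_fields else None,
            )
        )

    if traj.steady_time is None:
        res = detect_steady_state(traj)
        if res.steady:
            traj.steady_time = res.time
    return traj
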