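"""Experiment presets, replicate management and analysis fixtures.

The four simulation sets (neutralism, competition, commensalism, and
commensalism plus competition for O2) are expressed as presets over a
grid of bulk concentrations, run in seeded replicates.  Two scales are
provided:

* ``desk`` - a reduced problem that preserves the dimensionless regime of
  each condition at a fraction of the cost: a 71x71 grid at h = 2 um and
  a 30-cell / 20 um inoculum, run at the full bulk concentrations.  The
  fast default kinetics (division on the ~1 h timescale) put the
  substrate depletion length at a few to a few tens of micrometres, so
  each concentration label occupies the same position relative to the
  (smaller) aggregate radius as in a full-scale run, and every Monod
  saturation level and the eco-interaction modulus are untouched.
* ``paper`` - full-scale settings (larger grid, unscaled concentrations,
  multi-week horizons); provided for completeness, not exercised by the
  test suite.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (
    CellState,
    ConfigurationError,
    EcologyPreset,
    SimulationConfig,
    build_ecology_preset,
    mg_per_l_to_molar,
    DEFAULT_KINETICS,
    M_MAX_DEFAULT,
)
from .reaction_diffusion import GridSpec
from .scheduler import (
    AggregateSnapshot,
    SchedulerSettings,
    Trajectory,
    run_simulation,
)
from . import analysis, io as aio

__all__ = [
    "Scale",
    "DESK_SCALE",
    "PAPER_SCALE",
    "ExperimentPreset",
    "EXPERIMENT_PRESETS",
    "build_config",
    "load_config",
    "save_config",
    "run_experiment",
    "make_fixture",
    "steady_snapshot",
    "collect_condition_summary",
]


@dataclass(frozen=True)
class Scale:
    """Problem-size bundle: grid, inoculum, horizons, concentration factors."""

    name: str
    grid: GridSpec
    n_cells: int
    inoculum_diameter: float
    end_time: float  # h, default horizon
    concentration_factor: float  # applied to A-D bulk values
    o2_factor: float  # applied to O2 bulk values
    stop_radius: float | None
    snapshot_interval: float
    dt_bac_max: float


DESK_SCALE = Scale(
    name="desk",
    grid=GridSpec(nx=71, ny=71, h=2.0, boundary_layer_thickness=20.0),
    n_cells=30,
    inoculum_diameter=20.0,
    end_time=72.0,
    concentration_factor=1.0,
    o2_factor=1.0,
    stop_radius=42.0,
    snapshot_interval=2.0,
    dt_bac_max=0.5,
)

PAPER_SCALE = Scale(
    name="paper",
    grid=GridSpec(nx=257, ny=257, h=1.0, boundary_layer_thickness=20.0),
    n_cells=30,
    inoculum_diameter=20.0,
    end_time=1800.0,
    concentration_factor=1.0,
    o2_factor=1.0,
    stop_radius=100.0,
    snapshot_interval=12.0,
    dt_bac_max=0.5,
)

_SCALES = {"desk": DESK_SCALE, "paper": PAPER_SCALE}


def build_config(
    ecology_name: str,
    s_t_mm: float,
    o2_mg_l: float | None = None,
    *,
    seed: int,
    scale: Scale | str = DESK_SCALE,
    end_time: float | None = None,
    detachment_radius: float | None = None,
    stop_at_steady: bool = True,
    kinetics: dict | None = None,
    diffusivities: dict[str, float] | None = None,
    store_fields: bool = False,
) -> SimulationConfig:
    """Translate a paper-style condition label into a SimulationConfig.

    ``s_t_mm`` is the total substrate concentration label in mM and
    ``o2_mg_l`` the oxygen label in mg/L (mixed ecology only); both are
    multiplied by the scale's concentration factors.  Fed substrates per
    ecology: neutralism feeds A, B and C at [S]_T each; competition and
    commensalism feed only A; the mixed ecology feeds A and O2.
    """
    if isinstance(scale, str):
        scale = _SCALES[scale]
    conc = s_t_mm * 1e-3 * scale.concentration_factor
    if ecology_name == "neutralism":
        bulk = {"A": conc, "B": conc, "C": conc}
    elif ecology_name in ("competition", "commensalism"):
        bulk = {"A": conc}
    elif ecology_name == "commensalism_competition":
        if o2_mg_l is None:
            raise ConfigurationError("mixed ecology needs an O2 concentration")
        bulk = {"A": conc, "O2": mg_per_l_to_molar(o2_mg_l) * scale.o2_factor}
    else:
        raise ConfigurationError(f"unknown ecology {ecology_name!r}")

    ecology = build_ecology_preset(
        ecology_name, bulk, kinetics=kinetics, diffusivities=diffusivities
    )
    from .reaction_diffusion import RESIDUAL_ABS_TOL, SolverSettings

    solver = SolverSettings(
        residual_abs_tol=RESIDUAL_ABS_TOL * scale.concentration_factor
    )
    return SimulationConfig(
        ecology=ecology,
        grid=scale.grid,
        scheduler=SchedulerSettings(dt_bac_max=scale.dt_bac_max, solver=solver),
        seed=seed,
        end_time=scale.end_time if end_time is None else end_time,
        inoculum_diameter=scale.inoculum_diameter,
        n_cells=scale.n_cells,
        detachment_radius=detachment_radius,
        snapshot_interval=scale.snapshot_interval,
        stop_at_steady=stop_at_steady,
        stop_radius=scale.stop_radius,
        store_fields=store_fields,
    )


@dataclass(frozen=True)
class ExperimentPreset:
    """One of the simulation sets: ecology plus a concentration grid."""

    name: str
    ecology: str
    conditions: tuple[tuple[float, float | None], ...]  # (S_T mM, O2 mg/L)
    replicates: int = 3
    detachment_radius: float | None = None
    end_time: float | None = None
    scale: str = "desk"


EXPERIMENT_PRESETS = {
    "neutralism": ExperimentPreset(
        name="neutralism",
        ecology="neutralism",
        conditions=((1.0, None), (0.5, None), (0.2, None)),
    ),
    "competition": ExperimentPreset(
        name="competition",
        ecology="competition",
        conditions=((1.0, None), (0.5, None), (0.2, None), (0.1, None)),
    ),
    "commensalism": ExperimentPreset(
        name="commensalism",
        ecology="commensalism",
        conditions=((1.0, None), (0.5, None), (0.2, None), (0.1, None)),
    ),
    "mixed": ExperimentPreset(
        name="mixed",
        ecology="commensalism_competition",
        conditions=tuple(
            (s, o2) for s in (1.0, 0.5, 0.1, 0.05) for o2 in (10.0, 6.0, 1.0)
        ),
    ),
    "detachment": ExperimentPreset(
        name="detachment",
        ecology="commensalism",
        conditions=((0.1, None),),
        detachment_radius=30.0,
    ),
}


def _condition_label(s_t: float, o2: float | None) -> str:
    return f"S{s_t:g}mM" + (f"_O2_{o2:g}mgL" if o2 is not None else "")


def steady_snapshot(traj: Trajectory) -> AggregateSnapshot:
    """The snapshot at detected steady state, else the final one."""
    if traj.steady_time is not None:
        for s in traj.snapshots:
            if s.time >= traj.steady_time:
                return s
    return traj.final


def collect_condition_summary(
    trajectories: dict[tuple[str, int], Trajectory]
) -> pd.DataFrame:
    """Per (condition, replicate, population) steady-state summary rows."""
    rows = []
    for (label, rep), traj in trajectories.items():
        snap = steady_snapshot(traj)
        abund = analysis.relative_abundance(snap, active_only=True)
        try:
            colony = analysis.colony_size_summary(snap)
        except analysis.AnalysisError:
            colony = {}
        for name, a in abund.items():
            try:
                fit = analysis.fitness_median(snap, name)
            except analysis.AnalysisError:
                fit = math.nan
            rows.append(
                dict(
                    condition=label,
                    replicate=rep,
                    population=name,
                    abundance=a,
                    fitness_median=fit,
                    colony_rel_size=colony.get(name, math.nan),
                    time_h=snap.time,
                    steady_time_h=traj.steady_time,
                    n_cells=snap.cells.n,
                    radius_um=snap.radius,
                )
            )
    return pd.DataFrame(rows)


def run_experiment(
    preset: ExperimentPreset,
    base_seed: int,
    out_dir: str | Path | None = None,
    keep_trajectories: bool = True,
) -> dict:
    """Run one preset: one seeded run per (condition, replicate).

    Replicate seeds are ``base_seed + replicate_index`` so that paired
    presets (e.g. with and without detachment) start from identical
    inocula.  Failed runs are recorded and the remainder continue.
    Returns a dict with the merged summary frame, trajectories (optional)
    and failure records; writes per-run artefacts when ``out_dir`` given.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    trajectories: dict[tuple[str, int], Trajectory] = {}
    failures = []
    for s_t, o2 in preset.conditions:
        label = _condition_label(s_t, o2)
        for rep in range(preset.replicates):
            seed = base_seed + rep
            cfg = build_config(
                preset.ecology,
                s_t,
                o2,
                seed=seed,
                scale=preset.scale,
                end_time=preset.end_time,
                detachment_radius=preset.detachment_radius,
            )
            try:
                traj = run_simulation(cfg)
            except Exception as exc:  # noqa: BLE001 - record and continue
                failures.append(dict(condition=label, replicate=rep, error=str(exc)))
                continue
            trajectories[(label, rep)] = traj
            if out_path is not None:
                aio.save_trajectory(traj, out_path / label / f"rep{rep}")
    summary = collect_condition_summary(trajectories)
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_path / "summary.csv", index=False)
        (out_path / "failures.json").write_text(json.dumps(failures, indent=2))
    return {
        "summary": summary,
        "trajectories": trajectories if keep_trajectories else None,
        "failures": failures,
    }


# --- config files -----------------------------------------------------------


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML experiment description into a SimulationConfig.

    Sections: ``ecology`` (preset, bulk_concentrations in mol/L, optional
    kinetics and diffusivities overrides), ``grid``, ``scheduler``,
    ``shoving`` and ``run``; every default can be overridden and the seed
    is mandatory.
    """
    import yaml

    from .mechanics import ShovingSettings
    from .reaction_diffusion import SolverSettings

    raw = yaml.safe_load(Path(path).read_text()) or {}
    eco_sec = raw.get("ecology", {})
    if "preset" not in eco_sec:
        raise ConfigurationError("config needs ecology.preset")
    ecology = build_ecology_preset(
        eco_sec["preset"],
        {k: float(v) for k, v in eco_sec.get("bulk_concentrations", {}).items()},
        kinetics=eco_sec.get("kinetics"),
        diffusivities=eco_sec.get("diffusivities"),
    )
    grid = GridSpec(**{**dataclasses.asdict(DESK_SCALE.grid), **raw.get("grid", {})})
    sched_sec = dict(raw.get("scheduler", {}))
    solver = SolverSettings(**sched_sec.pop("solver", {}))
    scheduler = SchedulerSettings(solver=solver, **sched_sec)
    shoving = ShovingSettings(**raw.get("shoving", {}))
    run = dict(raw.get("run", {}))
    if "seed" not in run:
        raise ConfigurationError("config needs run.seed (archived runs are seeded)")
    return SimulationConfig(
        ecology=ecology, grid=grid, scheduler=scheduler, shoving=shoving, **run
    )


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a SimulationConfig back out as YAML (bulk values in mol/L)."""
    import yaml

    eco = config.ecology
    pop0 = eco.populations[0]
    doc = {
        "ecology": {
            "preset": eco.name,
            "bulk_concentrations": {
                k: v for k, v in eco.bulk_concentrations().items() if v > 0
            },
            "kinetics": {
                "mu_max": pop0.mu_max,
                "b_max": pop0.b_max,
                "Y_XS": pop0.Y_XS,
                "rho": pop0.rho,
                "M_max": pop0.M_max,
                "M_min": pop0.M_min,
            },
            "diffusivities": {
                s.name: s.diffusion_coefficient for s in eco.substrates
            },
        },
        "grid": dataclasses.asdict(config.grid),
        "scheduler": {
            **{
                k: v
                for k, v in dataclasses.asdict(config.scheduler).items()
                if k != "solver"
            },
            "solver": dataclasses.asdict(config.scheduler.solver),
        },
        "shoving": dataclasses.asdict(config.shoving)
        if config.shoving is not None
        else {},
        "run": {
            "seed": config.seed,
            "end_time": config.end_time,
            "n_cells": config.n_cells,
            "inoculum_diameter": config.inoculum_diameter,
            "detachment_radius": config.detachment_radius,
            "snapshot_interval": config.snapshot_interval,
            "stop_at_steady": config.stop_at_steady,
            "stop_radius": config.stop_radius,
            "store_fields": config.store_fields,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# --- analysis fixtures ------------------------------------------------------


def _fixture_snapshot(state: CellState, radius: float) -> AggregateSnapshot:
    summary = {"time_h": 0.0, "n_cells": state.n, "radius_um": radius}
    return AggregateSnapshot(
        time=0.0,
        cells=state,
        bulk={},
        centre=(0.0, 0.0),
        radius=radius,
        summary=summary,
    )


def make_fixture(kind: str, **params) -> AggregateSnapshot:
    """Synthetic snapshots with exact spatial patterns for analysis tests.

    Kinds: ``concentric`` (rings, B1 outermost - the layered pattern),
    ``sectors`` (pie sectors - the columned pattern), ``mixed``
    (deterministically interleaved labels) and ``random`` (seeded uniform
    random labels).  Masses are M_max/2 and growth rates decrease with
    depth, so fitness statistics behave like a real aggregate's.
    """
    pops = ("B1", "B2", "B3")
    if kind == "concentric":
        ring_radii = sorted(params.get("ring_radii", (3.0, 6.0, 9.0)))
        n_per_ring = int(params.get("n_per_ring", 60))
        xs, ys, labels = [], [], []
        # outermost ring belongs to B1, innermost to B3 (commensal layering)
        for pop_idx, r in enumerate(reversed(ring_radii)):
            ang = 2.0 * math.pi * np.arange(n_per_ring) / n_per_ring
            xs.append(r * np.cos(ang))
            ys.append(r * np.sin(ang))
            labels.append(np.full(n_per_ring, pop_idx))
        x, y, lab = map(np.concatenate, (xs, ys, labels))
        radius = max(ring_radii)
    elif kind == "sectors":
        n = int(params.get("n", 300))
        radius = float(params.get("radius", 10.0))
        n_sectors = int(params.get("n_sectors", 3))
        rng = np.random.default_rng(int(params.get("seed", 0)))
        r = radius * np.sqrt(rng.uniform(size=n))
        ang = rng.uniform(0.0, 2.0 * math.pi, size=n)
        x, y = r * np.cos(ang), r * np.sin(ang)
        lab = (np.degrees(ang) // (360.0 / n_sectors)).astype(int) % 3
    elif kind in ("mixed", "random"):
        n = int(params.get("n", 300))
        radius = float(params.get("radius", 10.0))
        rng = np.random.default_rng(int(params.get("seed", 0)))
        r = radius * np.sqrt(rng.uniform(size=n))
        ang = rng.uniform(0.0, 2.0 * math.pi, size=n)
        x, y = r * np.cos(ang), r * np.sin(ang)
        lab = (
            np.arange(n) % 3 if kind == "mixed" else rng.integers(0, 3, size=n)
        )
    else:
        raise ConfigurationError(f"unknown fixture kind {kind!r}")

    dist = np.hypot(x, y)
    if dist.size == 0 or radius <= 0:
        raise ConfigurationError("fixture geometry is empty")
    mu_max = DEFAULT_KINETICS["mu_max"]
    state = CellState(
        ids=np.arange(x.size),
        pop=lab,
        x=x,
        y=y,
        mass=np.full(x.size, M_MAX_DEFAULT / 2.0),
        active=np.ones(x.size, dtype=bool),
        mu=mu_max * (1.0 - 0.8 * dist / radius),  # shallower cells grow faster
        populations=pops,
    )
    return _fixture_snapshot(state, radius)
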