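"""Snapshot and trajectory serialization.

Cell tables go to CSV (one file per snapshot), concentration fields to an
HDF5 container (one dataset per substrate, grid metadata as attributes),
per-run summaries to a single CSV, and run metadata to JSON.  Transverse
concentration profiles can be exported as CSV for plotting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import CellState
from .scheduler import AggregateSnapshot, Trajectory

__all__ = [
    "save_trajectory",
    "write_cells_csv",
    "read_cells_csv",
    "write_fields_h5",
    "write_transverse_profile_csv",
    "load_run_summary",
    "load_snapshot_csvs",
    "render_snapshot",
]

#: figure colours per population, matching the aggregate renderings
POP_COLOURS = {"B1": "#7b3294", "B2": "#008837", "B3": "#e66101"}


def write_cells_csv(snapshot: AggregateSnapshot, path: Path, rho_by_pop=None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    snapshot.cells.to_frame(rho_by_pop).to_csv(path, index=False)


def read_cells_csv(path: Path) -> CellState:
    df = pd.read_csv(path)
    populations = tuple(sorted(df["population"].unique()))
    index = {p: i for i, p in enumerate(populations)}
    return CellState(
        ids=df["id"].to_numpy(),
        pop=df["population"].map(index).to_numpy(),
        x=df["x_um"].to_numpy(),
        y=df["y_um"].to_numpy(),
        mass=df["mass_mol"].to_numpy(),
        active=df["active"].to_numpy(bool),
        mu=df["mu_per_h"].to_numpy(),
        populations=populations,
    )


def write_fields_h5(snapshot: AggregateSnapshot, path: Path, grid) -> None:
    import h5py

    if snapshot.fields is None:
        raise ValueError("snapshot carries no fields (store_fields was off)")
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["time_h"] = snapshot.time
        f.attrs["h_um"] = grid.h
        f.attrs["nx"] = grid.nx
        f.attrs["ny"] = grid.ny
        f.attrs["boundary_layer_um"] = grid.boundary_layer_thickness
        for s in snapshot.fields.substrate_names:
            ds = f.create_dataset(s, data=snapshot.fields[s], chunks=True)
            ds.attrs["bulk_mol_per_l"] = snapshot.fields.bulk.get(s, 0.0)


def write_transverse_profile_csv(snapshot: AggregateSnapshot, path: Path, grid) -> None:
    """Concentration profile along the horizontal line through the centre."""
    if snapshot.fields is None:
        raise ValueError("snapshot carries no fields (store_fields was off)")
    xs, ys = grid.node_centres()
    jc = int(np.argmin(np.abs(ys - snapshot.centre[1])))
    data = {"x_um": xs}
    for s in snapshot.fields.substrate_names:
        data[s] = snapshot.fields[s][:, jc]
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(data).to_csv(path, index=False)


def save_trajectory(traj: Trajectory, out_dir: str | Path) -> Path:
    """Write one run: per-snapshot cell CSVs, optional field containers,
    a summary CSV and run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ecology = traj.config.ecology
    rho = np.array([p.rho for p in ecology.populations])
    for snap in traj.snapshots:
        stem = f"t{snap.time:09.2f}"
        write_cells_csv(snap, out / "snapshots" / f"{stem}_cells.csv", rho)
        if snap.fields is not None:
            write_fields_h5(snap, out / "fields" / f"{stem}.h5", traj.config.grid)
    traj.summary_frame().to_csv(out / "summary.csv", index=False)
    meta = {
        "ecology": ecology.name,
        "seed": traj.config.seed,
        "end_time_h": traj.config.end_time,
        "detachment_radius_um": traj.config.detachment_radius,
        "steady_time_h": traj.steady_time,
        "stop_reason": traj.stop_reason,
        "bulk_mol_per_l": ecology.bulk_concentrations(),
    }
    (out / "run.json").write_text(json.dumps(meta, indent=2))
    return out


def load_run_summary(run_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "summary.csv")


def load_snapshot_csvs(run_dir: str | Path) -> list[tuple[float, CellState]]:
    """(time, cells) pairs for every stored snapshot, in time order."""
    files = sorted((Path(run_dir) / "snapshots").glob("t*_cells.csv"))
    out = []
    for f in files:
        t = float(f.name[1:].split("_")[0])
        out.append((t, read_cells_csv(f)))
    return out


def render_snapshot(
    snapshot: AggregateSnapshot,
    path: str | Path,
    rho_by_pop: np.ndarray,
    dpi: int = 150,
) -> None:
    """PNG rendering: active cells in full colour, inactive lighter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import EllipseCollection

    cells = snapshot.cells
    radii = cells.radii(rho_by_pop)
    fig, ax = plt.subplots(figsize=(5, 5))
    colours = []
    for i in range(cells.n):
        base = POP_COLOURS.get(cells.populations[cells.pop[i]], "#555555")
        colours.append(base if cells.active[i] else base + "55")
    ec = EllipseCollection(
        widths=2 * radii,
        heights=2 * radii,
        angles=0,
        units="xy",
        offsets=np.column_stack([cells.x, cells.y]),
        transOffset=ax.transData,
        facecolors=colours,
        edgecolors="none",
    )
    ax.add_collection(ec)
    lim = snapshot.radius * 1.2 + 2
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"t = {snapshot.time:.1f} h, n = {cells.n}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
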