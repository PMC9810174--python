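"""Pseudo-steady diffusion-reaction solver on a uniform 2D grid.

Soluble components obey Fick's second law with a biological reaction term,

    d(phi)/dt = D * laplacian(phi) + R(x, y, t),

solved to pseudo-steady state on every outer biology step.  The domain is
split into three zones - aggregate, boundary layer and bulk liquid.  Bulk
nodes are pinned to the bulk concentration (Dirichlet); diffusion and
reaction are resolved in the other two.  The discrete residual on a
diffusion-region node is

    RES_ij = (phi_N + phi_S + phi_E + phi_W - 4 phi_ij) + (h^2 / D) R_ij

and pseudo-steady state is declared when on every diffusion node

    |RES_ij| <= 1% * phi_ij   where phi_ij >> 1e-6,
    |RES_ij| <= 1e-6          where phi_ij is of order 1e-6 or below,

implemented as |RES| <= max(1e-6, 0.01 * phi).

Two solver strategies are available: a direct sparse LU of the five-point
Laplacian (factorized once per zone relabelling and shared by all
substrates, since the dimensionless operator does not depend on D) with
Picard iteration on the Monod reaction term, and a damped Jacobi iteration
that refreshes the reaction term every ``n`` sweeps.  Both must satisfy the
same residual rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_core import (
    CellState,
    EcologyPreset,
    ConfigurationError,
    IntegrityError,
    DOMAIN_DEPTH_UM,
    L_PER_UM3,
)

__all__ = [
    "GridSpec",
    "Zones",
    "ConcentrationField",
    "ResidualReport",
    "SolverError",
    "SolverSettings",
    "PoissonOperator",
    "assemble_reaction_term",
    "compute_growth_rates",
    "solve_pseudo_steady",
    "boundary_flux_balance",
    "ZONE_AGGREGATE",
    "ZONE_BOUNDARY_LAYER",
    "ZONE_BULK",
]

ZONE_AGGREGATE = 0
ZONE_BOUNDARY_LAYER = 1
ZONE_BULK = 2

#: Eq-9 style tolerances: relative where the concentration is appreciable,
#: absolute on near-zero nodes
RESIDUAL_REL_TOL = 0.01
RESIDUAL_ABS_TOL = 1e-6


class SolverError(RuntimeError):
    """Pseudo-steady solve failed to converge; carries the residual report."""

    def __init__(self, message: str, report: "ResidualReport"):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid geometry: node size, node counts, boundary-layer width.

    Node (i, j) covers the half-open square [x_i, x_i + h) x [y_j, y_j + h),
    with the domain centred on the origin; a cell belongs to exactly one
    node, the one whose half-open square contains its centre.
    """

    nx: int
    ny: int
    h: float  # um
    boundary_layer_thickness: float = 20.0  # um

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ConfigurationError("node size h must be > 0")
        if self.nx < 3 or self.ny < 3:
            raise ConfigurationError("grid must be at least 3x3")

    @property
    def extent_x(self) -> float:
        return self.nx * self.h

    @property
    def extent_y(self) -> float:
        return self.ny * self.h

    @property
    def node_volume_l(self) -> float:
        """Node volume (h^2 times unit depth) in litres."""
        return self.h * self.h * DOMAIN_DEPTH_UM * L_PER_UM3

    def node_centres(self) -> tuple[np.ndarray, np.ndarray]:
        xs = (np.arange(self.nx) + 0.5) * self.h - self.extent_x / 2.0
        ys = (np.arange(self.ny) + 0.5) * self.h - self.extent_y / 2.0
        return xs, ys

    def node_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open node ownership; raises if any point is off-grid."""
        ix = np.floor((np.asarray(x) + self.extent_x / 2.0) / self.h).astype(np.int64)
        iy = np.floor((np.asarray(y) + self.extent_y / 2.0) / self.h).astype(np.int64)
        if np.any((ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)):
            raise IntegrityError("cell centre outside the simulation grid")
        return ix, iy

    def label_zones(self, centre: tuple[float, float], aggregate_radius: float) -> "Zones":
        """Label nodes aggregate / boundary layer / bulk around ``centre``.

        Raises :class:`IntegrityError` when the boundary layer no longer fits
        inside the grid (no bulk node ring left on some side).
        """
        xs, ys = self.node_centres()
        dx = xs[:, None] - centre[0]
        dy = ys[None, :] - centre[1]
        dist = np.hypot(dx, dy)
        labels = np.full((self.nx, self.ny), ZONE_BULK, dtype=np.int8)
        labels[dist <= aggregate_radius + self.boundary_layer_thickness] = (
            ZONE_BOUNDARY_LAYER
        )
        labels[dist <= aggregate_radius] = ZONE_AGGREGATE
        edge = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        if np.any(edge != ZONE_BULK):
            raise IntegrityError(
                "aggregate plus boundary layer exceeds the simulation grid"
            )
        return Zones(labels=labels, centre=centre, aggregate_radius=aggregate_radius)


@dataclass
class Zones:
    """Per-node zone labels for one aggregate geometry."""

    labels: np.ndarray  # (nx, ny) int8
    centre: tuple[float, float]
    aggregate_radius: float

    @property
    def diffusion_mask(self) -> np.ndarray:
        return self.labels != ZONE_BULK


class ConcentrationField:
    """Per-substrate gridded concentrations (mol/L) plus bulk values."""

    def __init__(self, substrate_names, shape, bulk: dict[str, float]):
        self.substrate_names = tuple(substrate_names)
        self.bulk = dict(bulk)
        self.data = {
            s: np.full(shape, self.bulk.get(s, 0.0), dtype=float)
            for s in self.substrate_names
        }

    @classmethod
    def from_ecology(cls, ecology: EcologyPreset, grid: GridSpec) -> "ConcentrationField":
        return cls(
            ecology.substrate_names,
            (grid.nx, grid.ny),
            ecology.bulk_concentrations(),
        )

    def __getitem__(self, substrate: str) -> np.ndarray:
        return self.data[substrate]

    def __setitem__(self, substrate: str, value: np.ndarray) -> None:
        self.data[substrate] = np.asarray(value, dtype=float)

    def copy(self) -> "ConcentrationField":
        out = ConcentrationField(self.substrate_names, next(iter(self.data.values())).shape, self.bulk)
        for s in self.substrate_names:
            out.data[s] = self.data[s].copy()
        return out

    def set_bulk(self, substrate: str, value: float) -> None:
        self.bulk[substrate] = float(value)

    def pin_bulk(self, zones: Zones) -> None:
        """Reset bulk-zone nodes to the Dirichlet value."""
        bulk_nodes = zones.labels == ZONE_BULK
        for s in self.substrate_names:
            self.data[s][bulk_nodes] = self.bulk.get(s, 0.0)


@dataclass
class ResidualReport:
    """Outcome of one pseudo-steady solve."""

    max_residual: dict[str, float]
    converged: bool
    iterations: int

    def worst(self) -> float:
        return max(self.max_residual.values()) if self.max_residual else 0.0


@dataclass
class SolverSettings:
    method: str = "direct"  # or "jacobi"
    max_picard: int = 200
    reaction_refresh_n: int = 10  # jacobi sweeps between reaction refreshes
    max_jacobi_sweeps: int = 200_000
    jacobi_damping: float = 1.0
    #: absolute residual floor of the tolerance rule (mol/L).  1e-6 matches
    #: full-scale concentrations; a rescaled (desk) problem scales it by the
    #: same concentration factor so near-zero nodes stay resolved.
    residual_abs_tol: float = RESIDUAL_ABS_TOL


# --- growth rates and reaction assembly ------------------------------------


def _as_state(cells, ecology: EcologyPreset) -> CellState:
    if isinstance(cells, CellState):
        return cells
    pops = tuple(p.name for p in ecology.populations)
    return CellState.from_cells(list(cells), pops)


def compute_growth_rates(
    state: CellState,
    fields: ConcentrationField,
    ecology: EcologyPreset,
    grid: GridSpec,
) -> np.ndarray:
    """Provisional net growth rate (1/h) of every cell from its node's
    concentrations: mu = mu_max * prod Monod * prod inhibition - b.

    Computed for inactive cells too (their reactivation trigger); the caller
    decides what to do with activity.
    """
    ix, iy = grid.node_of(state.x, state.y)
    mu = np.empty(state.n, dtype=float)
    for p_idx, pop in enumerate(ecology.populations):
        sel = state.pop == p_idx
        if not np.any(sel):
            continue
        m = np.full(sel.sum(), pop.mu_max)
        for s, ks in pop.K_S.items():
            phi = fields[s][ix[sel], iy[sel]]
            m *= phi / (ks + phi)
        for s, ki in pop.K_I.items():
            phi = fields[s][ix[sel], iy[sel]]
            m *= ki / (ki + phi)
        mu[sel] = m - pop.b_max
    return mu


def assemble_reaction_term(
    cells,
    fields: ConcentrationField,
    ecology: EcologyPreset,
    grid: GridSpec,
    mu: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-node, per-substrate volumetric rates (mol/L/h).

    Each cell contributes stoich(pop, s) * mu_gross * X / V_node to the
    single node owning its centre, where mu_gross = mu + b is the gross
    catabolic rate (growth plus maintenance); inactive cells contribute
    nothing.
    """
    state = _as_state(cells, ecology)
    if mu is None:
        mu = compute_growth_rates(state, fields, ecology, grid)
    ix, iy = grid.node_of(state.x, state.y)
    # substrate turnover follows the gross (catabolic) rate mu + b: a
    # maintaining cell keeps consuming even when its net growth is zero or
    # negative, which lets deep zones starve below the subsistence level
    b = np.array([p.b_max for p in ecology.populations])[state.pop]
    rate = state.mass * np.maximum(mu + b, 0.0) / grid.node_volume_l  # mol X/L/h
    rate = np.where(state.active, rate, 0.0)

    shape = (grid.nx, grid.ny)
    reaction = {s: np.zeros(shape) for s in fields.substrate_names}
    for p_idx, pop in enumerate(ecology.populations):
        sel = state.pop == p_idx
        if not np.any(sel):
            continue
        for s, coeff in pop.stoichiometry.items():
            np.add.at(reaction[s], (ix[sel], iy[sel]), coeff * rate[sel])
    return reaction


def linearized_reaction_terms(
    state: CellState,
    fields: ConcentrationField,
    ecology: EcologyPreset,
    grid: GridSpec,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Split the reaction into explicit production and a linearized sink.

    For each substrate the consumption of a cell is written k * phi with
    k = |coeff| * mu_hat * X / (V (K_S + phi_old)), where mu_hat is the
    gross catabolic rate with the substrate's own Monod factor removed;
    production keeps the frozen rate.  At the fixed point of the resulting
    iteration the sink equals the exact nonlinear Monod consumption.
    """
    ix, iy = grid.node_of(state.x, state.y)
    shape = (grid.nx, grid.ny)
    production = {s: np.zeros(shape) for s in fields.substrate_names}
    sink = {s: np.zeros(shape) for s in fields.substrate_names}
    vol = grid.node_volume_l

    for p_idx, pop in enumerate(ecology.populations):
        sel = (state.pop == p_idx) & state.active
        if not np.any(sel):
            continue
        jx, jy = ix[sel], iy[sel]
        mono = {}
        for s, ks in pop.K_S.items():
            phi = fields[s][jx, jy]
            mono[s] = phi / (ks + phi)
        inh = np.ones(sel.sum())
        for s, ki in pop.K_I.items():
            phi = fields[s][jx, jy]
            inh *= ki / (ki + phi)
        mu_gross = pop.mu_max * inh
        for s in mono:
            mu_gross = mu_gross * mono[s]
        rate = mu_gross * state.mass[sel] / vol  # mol X / L / h
        for s, coeff in pop.stoichiometry.items():
            if coeff > 0:
                np.add.at(production[s], (jx, jy), coeff * rate)
            else:
                # exclusion product: gross rate without this substrate's factor
                mu_hat = pop.mu_max * inh
                for u, m in mono.items():
                    if u != s:
                        mu_hat = mu_hat * m
                phi_old = fields[s][jx, jy]
                k = (
                    -coeff
                    * mu_hat
                    * state.mass[sel]
                    / (vol * (pop.K_S[s] + phi_old))
                )
                np.add.at(sink[s], (jx, jy), k)
    return production, sink


# --- linear operator --------------------------------------------------------


class PoissonOperator:
    """Five-point Laplacian over the diffusion region with Dirichlet bulk.

    The dimensionless system  (sum of neighbours - 4 phi) = -(h^2/D) R  is
    independent of D, so a single LU factorization serves every substrate;
    only the right-hand side changes.
    """

    def __init__(self, grid: GridSpec, zones: Zones):
        self.grid = grid
        self.zones = zones
        mask = zones.diffusion_mask
        self.mask = mask
        nx, ny = grid.nx, grid.ny
        idx = -np.ones((nx, ny), dtype=np.int64)
        ii, jj = np.nonzero(mask)
        n_unk = ii.size
        idx[ii, jj] = np.arange(n_unk)
        self.index = idx
        self.nodes = (ii, jj)

        rows, cols, vals = [], [], []
        # count of Dirichlet neighbours per unknown (uniform bulk value)
        bulk_nb = np.zeros(n_unk)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = ii + di, jj + dj
            inside = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny)
            # diffusion region never touches the grid edge (checked in
            # label_zones), so out-of-range neighbours cannot occur; keep the
            # guard for standalone use of the operator on custom masks
            nb_idx = np.where(inside, idx[ni % nx, nj % ny], -1)
            known = inside & (nb_idx < 0)
            unknown = nb_idx >= 0
            rows.extend(np.arange(n_unk)[unknown])
            cols.extend(nb_idx[unknown])
            vals.extend(np.ones(int(unknown.sum())))
            bulk_nb += known.astype(float)
        rows.extend(np.arange(n_unk))
        cols.extend(np.arange(n_unk))
        vals.extend(np.full(n_unk, -4.0))
        A = sp.csc_matrix(
            (np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
            shape=(n_unk, n_unk),
        )
        self.A = A
        self.bulk_neighbour_count = bulk_nb
        self._lu = spla.splu(A)

    def solve(self, reaction: np.ndarray, diffusivity: float, bulk_value: float) -> np.ndarray:
        """Steady field for one substrate with a frozen reaction term."""
        h2_over_d = self.grid.h**2 / diffusivity
        ii, jj = self.nodes
        rhs = -h2_over_d * reaction[ii, jj] - self.bulk_neighbour_count * bulk_value
        phi_unknown = self._lu.solve(rhs)
        out = np.full((self.grid.nx, self.grid.ny), bulk_value, dtype=float)
        out[ii, jj] = phi_unknown
        return out

    def solve_with_sink(
        self,
        production: np.ndarray,
        sink_coeff: np.ndarray,
        diffusivity: float,
        bulk_value: float,
    ) -> np.ndarray:
        """Steady field with explicit production and linearized consumption.

        Solves  (L - diag(h^2/D * k)) phi = -(h^2/D) P - dirichlet terms,
        where the sink rate is k * phi (k >= 0, 1/h).  The matrix stays an
        M-matrix, so the solution is non-negative for non-negative inputs.
        """
        h2_over_d = self.grid.h**2 / diffusivity
        ii, jj = self.nodes
        sink = np.maximum(sink_coeff[ii, jj], 0.0)
        rhs = (
            -h2_over_d * np.maximum(production[ii, jj], 0.0)
            - self.bulk_neighbour_count * bulk_value
        )
        if np.any(sink > 0.0):
            A = self.A - sp.diags(h2_over_d * sink, format="csc")
            phi_unknown = spla.splu(A).solve(rhs)
        else:
            phi_unknown = self._lu.solve(rhs)
        out = np.full((self.grid.nx, self.grid.ny), bulk_value, dtype=float)
        out[ii, jj] = phi_unknown
        return out

    def laplacian(self, phi: np.ndarray) -> np.ndarray:
        """Dimensionless 5-point Laplacian on diffusion nodes (flat array)."""
        ii, jj = self.nodes
        nx, ny = self.grid.nx, self.grid.ny
        lap = -4.0 * phi[ii, jj]
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = np.clip(ii + di, 0, nx - 1), np.clip(jj + dj, 0, ny - 1)
            lap += phi[ni, nj]
        return lap

    def residual(self, phi: np.ndarray, reaction: np.ndarray, diffusivity: float) -> np.ndarray:
        ii, jj = self.nodes
        return self.laplacian(phi) + self.grid.h**2 / diffusivity * reaction[ii, jj]


def _tolerances(phi_nodes: np.ndarray, abs_tol: float = RESIDUAL_ABS_TOL) -> np.ndarray:
    return np.maximum(abs_tol, RESIDUAL_REL_TOL * phi_nodes)


# --- pseudo-steady solve ----------------------------------------------------


def solve_pseudo_steady(
    fields: ConcentrationField,
    cells,
    ecology: EcologyPreset,
    grid: GridSpec,
    settings: SolverSettings | None = None,
    zones: Zones | None = None,
    operator: PoissonOperator | None = None,
) -> tuple[ConcentrationField, ResidualReport]:
    """Drive all substrate fields to pseudo-steady state.

    Returns the updated fields and a :class:`ResidualReport`; raises
    :class:`SolverError` (carrying the report) on non-convergence.  The
    input ``fields`` object is updated in place and also returned.
    """
    settings = settings or SolverSettings()
    state = _as_state(cells, ecology)
    if operator is None:
        if zones is None:
            from .mechanics import aggregate_centre_and_radius

            centre, radius = aggregate_centre_and_radius(state, ecology)
            zones = grid.label_zones(centre, radius)
        operator = PoissonOperator(grid, zones)
    fields.pin_bulk(operator.zones)

    if settings.method == "direct":
        return _solve_direct(fields, state, ecology, grid, settings, operator)
    if settings.method == "jacobi":
        return _solve_jacobi(fields, state, ecology, grid, settings, operator)
    raise ConfigurationError(f"unknown solver method {settings.method!r}")


def _max_residuals(
    operator, fields, reaction, ecology, abs_tol
) -> tuple[dict, bool, float]:
    """Per-substrate max |residual|, the tolerance verdict, and the worst
    residual-to-tolerance ratio (<= 1 means converged)."""
    ii, jj = operator.nodes
    maxres = {}
    worst_ratio = 0.0
    for sub in ecology.substrates:
        phi = fields[sub.name]
        res = np.abs(operator.residual(phi, reaction[sub.name], sub.diffusion_coefficient))
        maxres[sub.name] = float(res.max()) if res.size else 0.0
        if res.size:
            ratio = float(np.max(res / _tolerances(phi[ii, jj], abs_tol)))
            worst_ratio = max(worst_ratio, ratio)
    return maxres, worst_ratio <= 1.0, worst_ratio


def _solve_direct(fields, state, ecology, grid, settings, operator):
    theta = 1.0  # field under-relaxation, reduced when the residual stalls
    best_ratio = math.inf
    since_best = 0
    for it in range(1, settings.max_picard + 1):
        mu = compute_growth_rates(state, fields, ecology, grid)
        reaction = assemble_reaction_term(state, fields, ecology, grid, mu=mu)
        maxres, ok, ratio = _max_residuals(
            operator, fields, reaction, ecology, settings.residual_abs_tol
        )
        if ok:
            return fields, ResidualReport(maxres, True, it - 1)
        # damp when no meaningful progress over a few iterations (catches
        # period-2 Picard oscillation at stiff Monod depletion fronts) and
        # recover once the iteration is contracting again
        if ratio < 0.9 * best_ratio:
            best_ratio = ratio
            since_best = 0
            theta = min(1.0, 1.3 * theta)
        else:
            since_best += 1
            if since_best >= 3:
                theta = max(0.5 * theta, 0.05)
                since_best = 0
        production, sink = linearized_reaction_terms(state, fields, ecology, grid)
        for sub in ecology.substrates:
            name = sub.name
            bulk = fields.bulk.get(name, 0.0)
            if (
                not np.any(production[name])
                and not np.any(sink[name])
                and np.all(fields[name][operator.nodes] == bulk)
            ):
                continue  # untouched substrate: already uniform at bulk
            phi = operator.solve_with_sink(
                production[name], sink[name], sub.diffusion_coefficient, bulk
            )
            np.maximum(phi, 0.0, out=phi)
            fields[name] = theta * phi + (1.0 - theta) * fields[name]
    report = ResidualReport(maxres, False, settings.max_picard)
    raise SolverError("pseudo-steady solve did not converge", report)


def _solve_jacobi(fields, state, ecology, grid, settings, operator):
    ii, jj = operator.nodes
    n_refresh = max(1, settings.reaction_refresh_n)
    omega = settings.jacobi_damping
    sweeps = 0
    while sweeps < settings.max_jacobi_sweeps:
        mu = compute_growth_rates(state, fields, ecology, grid)
        reaction = assemble_reaction_term(state, fields, ecology, grid, mu=mu)
        maxres, ok, _ratio = _max_residuals(
            operator, fields, reaction, ecology, settings.residual_abs_tol
        )
        if ok:
            return fields, ResidualReport(maxres, True, sweeps)
        for _ in range(n_refresh):
            for sub in ecology.substrates:
                phi = fields[sub.name]
                h2_over_d = grid.h**2 / sub.diffusion_coefficient
                nb = operator.laplacian(phi) + 4.0 * phi[ii, jj]
                target = (nb + h2_over_d * reaction[sub.name][ii, jj]) / 4.0
                phi[ii, jj] = np.maximum(
                    (1 - omega) * phi[ii, jj] + omega * target, 0.0
                )
            sweeps += 1
    reaction = assemble_reaction_term(state, fields, ecology, grid)
    maxres, ok, _ratio = _max_residuals(
        operator, fields, reaction, ecology, settings.residual_abs_tol
    )
    report = ResidualReport(maxres, ok, sweeps)
    if ok:
        return fields, report
    raise SolverError("Jacobi iteration did not converge", report)


# --- conservation diagnostic ------------------------------------------------


def boundary_flux_balance(
    fields: ConcentrationField,
    reaction: dict[str, np.ndarray],
    grid: GridSpec,
    zones: Zones,
    diffusivities: dict[str, float],
) -> dict[str, dict[str, float]]:
    """Net diffusive influx across the Dirichlet rim vs total reaction.

    For a converged pseudo-steady field the influx (mol/h) through the rim
    balances the net reaction inside the diffusion region; the returned
    ``imbalance`` is influx + total_reaction (zero at exact steady state,
    consumption being negative).
    """
    mask = zones.diffusion_mask
    nx, ny = grid.nx, grid.ny
    out = {}
    vol = grid.node_volume_l
    conc_factor = L_PER_UM3  # mol/L -> mol/um^3
    for s in fields.substrate_names:
        phi = fields[s]
        bulk = fields.bulk.get(s, 0.0)
        influx = 0.0
        d = diffusivities[s]
        ii, jj = np.nonzero(mask)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = ii + di, jj + dj
            inside = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny)
            is_bulk_nb = np.zeros(ii.shape, dtype=bool)
            is_bulk_nb[inside] = ~mask[ni[inside], nj[inside]]
            if np.any(is_bulk_nb):
                dphi = bulk - phi[ii[is_bulk_nb], jj[is_bulk_nb]]
                # D * grad(c) * face area, with unit depth
                influx += float(
                    np.sum(d * dphi * conc_factor / grid.h * grid.h * DOMAIN_DEPTH_UM)
                )
        total_reaction = float(np.sum(reaction[s][mask]) * vol)
        out[s] = {
            "influx_mol_per_h": influx,
            "reaction_mol_per_h": total_reaction,
            "imbalance_mol_per_h": influx + total_reaction,
        }
    return out
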