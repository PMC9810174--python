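"""Per-cell biology: Monod growth, Euler mass integration, division,
inactivation and reactivation.

Each microbe's actual growth rate follows multiplicative Monod kinetics
over its consumed substrates, with optional non-competitive inhibition and
a maintenance deduction:

    mu = mu_max * prod_s [phi_s / (K_S + phi_s)]
               * prod_i [K_I / (K_I + phi_i)]  -  b

Mass is integrated with forward Euler, X <- X * (1 + mu * dt).  A cell
reaching its maximum mass M_max divides, handing a stochastic fraction
alpha ~ U(0.45, 0.55) of its mass to a daughter placed at a uniformly
random angle adjacent to the parent.  A cell shrinking to its minimum mass
M_min becomes inactive - it neither grows nor decays and contributes
nothing to the reaction term - and reactivates only when local conditions
would again give it a positive growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import Cell, CellState, PopulationSpec

__all__ = [
    "DivisionEvent",
    "ALPHA_LOW",
    "ALPHA_HIGH",
    "growth_rate",
    "integrate_mass",
    "radius_from_mass",
    "maybe_divide",
    "place_daughter",
    "update_activity",
    "advance_masses",
    "apply_activity_rules",
    "perform_divisions",
]

#: division mass-split fraction bounds
ALPHA_LOW = 0.45
ALPHA_HIGH = 0.55


@dataclass(frozen=True)
class DivisionEvent:
    """Record of one division: who split, how much, and where."""

    parent_id: int
    daughter_id: int
    alpha: float  # daughter's mass fraction, in [0.45, 0.55]
    angle: float  # placement angle, radians

    def __post_init__(self) -> None:
        if not (ALPHA_LOW <= self.alpha <= ALPHA_HIGH):
            raise ValueError("alpha outside the stochastic split range")


# --- scalar operations ------------------------------------------------------


def growth_rate(cell: Cell, local_conc: dict[str, float], spec: PopulationSpec) -> float:
    """Actual net growth rate (1/h) of one cell from local concentrations.

    May be negative (maintenance-dominated decay).  Inactive cells are the
    caller's concern: their mu is treated as zero in reaction terms.
    """
    mu = spec.mu_max
    for s, ks in spec.K_S.items():
        phi = local_conc.get(s, 0.0)
        mu *= phi / (ks + phi)
    for s, ki in spec.K_I.items():
        phi = local_conc.get(s, 0.0)
        mu *= ki / (ki + phi)
    return mu - spec.b_max


def integrate_mass(cell: Cell, mu: float, dt_bac: float) -> Cell:
    """One forward-Euler mass step; mass is floored at zero."""
    if dt_bac <= 0:
        raise ValueError("dt_bac must be > 0")
    new_mass = max(cell.mass * (1.0 + mu * dt_bac), 0.0)
    return Cell(
        id=cell.id,
        population=cell.population,
        x=cell.x,
        y=cell.y,
        mass=new_mass,
        active=cell.active,
        mu_current=mu,
    )


def radius_from_mass(mass: float, rho: float) -> float:
    """Radius (um) of a sphere of the given biomass and density."""
    if mass < 0 or rho <= 0:
        raise ValueError("need mass >= 0 and rho > 0")
    return (mass / rho * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def maybe_divide(
    cell: Cell,
    rng: np.random.Generator,
    m_max: float | None = None,
    daughter_id: int | None = None,
) -> DivisionEvent | None:
    """Check the division trigger and draw the stochastic split.

    Returns ``None`` below M_max.  The split fraction alpha is uniform on
    [0.45, 0.55] and the daughter angle uniform on [0, 2 pi).
    """
    from .model_core import M_MAX_DEFAULT

    if cell.mass < (M_MAX_DEFAULT if m_max is None else m_max):
        return None
    alpha = float(rng.uniform(ALPHA_LOW, ALPHA_HIGH))
    angle = float(rng.uniform(0.0, 2.0 * math.pi))
    return DivisionEvent(
        parent_id=cell.id,
        daughter_id=cell.id + 1 if daughter_id is None else daughter_id,
        alpha=alpha,
        angle=angle,
    )


def place_daughter(cell: Cell, event: DivisionEvent, rho: float) -> tuple[Cell, Cell]:
    """Apply a division event: returns (updated parent, daughter).

    The daughter is placed at centre distance r_parent + r_daughter
    (post-split radii) at the event's angle; any overlap with third cells
    is resolved by the subsequent shoving pass.  Total mass is conserved
    exactly.
    """
    m_d = event.alpha * cell.mass
    m_p = cell.mass - m_d
    r_p = radius_from_mass(m_p, rho)
    r_d = radius_from_mass(m_d, rho)
    dist = r_p + r_d
    daughter = Cell(
        id=event.daughter_id,
        population=cell.population,
        x=cell.x + dist * math.cos(event.angle),
        y=cell.y + dist * math.sin(event.angle),
        mass=m_d,
        active=True,
        mu_current=cell.mu_current,
    )
    parent = Cell(
        id=cell.id,
        population=cell.population,
        x=cell.x,
        y=cell.y,
        mass=m_p,
        active=cell.active,
        mu_current=cell.mu_current,
    )
    return parent, daughter


def update_activity(cell: Cell, mu: float, m_min: float) -> Cell:
    """Inactivation / reactivation rules.

    An active cell whose mass has fallen to M_min (or below) inactivates;
    an inactive cell whose provisional growth rate is positive becomes
    active again.  Inactive cells keep constant mass and report mu = 0.
    """
    active = cell.active
    if active and cell.mass <= m_min:
        active = False
    if not active and mu > 0.0:
        active = True
    return Cell(
        id=cell.id,
        population=cell.population,
        x=cell.x,
        y=cell.y,
        mass=cell.mass,
        active=active,
        mu_current=mu if active else 0.0,
    )


# --- vectorized engine paths ------------------------------------------------


def advance_masses(state: CellState, mu: np.ndarray, dt_bac: float) -> None:
    """Forward-Euler mass update of all active cells, in place."""
    growing = state.active
    state.mass[growing] = np.maximum(
        state.mass[growing] * (1.0 + mu[growing] * dt_bac), 0.0
    )
    state.mu = np.where(state.active, mu, 0.0)


def apply_activity_rules(state: CellState, mu: np.ndarray, m_min_by_pop: np.ndarray) -> None:
    """Vectorized inactivation-then-reactivation, in place."""
    m_min = m_min_by_pop[state.pop]
    state.active = state.active & ~(state.mass <= m_min)
    state.active = state.active | (mu > 0.0)
    state.mu = np.where(state.active, mu, 0.0)


def perform_divisions(
    state: CellState,
    rng: np.random.Generator,
    specs: list[PopulationSpec],
    next_id: int,
) -> tuple[CellState, list[DivisionEvent], int]:
    """Divide every cell at or above its population's M_max.

    Returns the enlarged state (daughters appended in parent order), the
    division events, and the next free cell id.  Biomass is conserved to
    machine precision.
    """
    m_max = np.array([s.M_max for s in specs])[state.pop]
    dividing = np.nonzero(state.mass >= m_max)[0]
    if dividing.size == 0:
        return state, [], next_id

    alphas = rng.uniform(ALPHA_LOW, ALPHA_HIGH, size=dividing.size)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=dividing.size)
    rho = np.array([s.rho for s in specs])[state.pop[dividing]]

    m_daughter = alphas * state.mass[dividing]
    m_parent = state.mass[dividing] - m_daughter
    r_p = np.cbrt(m_parent / rho * 3.0 / (4.0 * math.pi))
    r_d = np.cbrt(m_daughter / rho * 3.0 / (4.0 * math.pi))
    dist = r_p + r_d

    events = [
        DivisionEvent(
            parent_id=int(state.ids[i]),
            daughter_id=next_id + k,
            alpha=float(alphas[k]),
            angle=float(angles[k]),
        )
        for k, i in enumerate(dividing)
    ]

    state.mass[dividing] = m_parent
    new = CellState(
        ids=next_id + np.arange(dividing.size),
        pop=state.pop[dividing],
        x=state.x[dividing] + dist * np.cos(angles),
        y=state.y[dividing] + dist * np.sin(angles),
        mass=m_daughter,
        active=np.ones(dividing.size, dtype=bool),
        mu=state.mu[dividing],
        populations=state.populations,
    )
    merged = CellState(
        ids=np.concatenate([state.ids, new.ids]),
        pop=np.concatenate([state.pop, new.pop]),
        x=np.concatenate([state.x, new.x]),
        y=np.concatenate([state.y, new.y]),
        mass=np.concatenate([state.mass, new.mass]),
        active=np.concatenate([state.active, new.active]),
        mu=np.concatenate([state.mu, new.mu]),
        populations=state.populations,
    )
    return merged, events, next_id + dividing.size
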