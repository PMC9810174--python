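"""Domain types, unit conventions, ecology presets and the inoculum generator.

Unit system (used consistently across the package):

* length        micrometre (um)
* time          hour (h)
* cell mass     mole of biomass (mol)
* concentration mol per litre (mol/L); helpers convert mM and mg/L inputs
* diffusivity   um^2/h internally; config files may give m^2/h

The simulated community is the three-population system B1, B2, B3 with
identical growth kinetics ("theoretical equal-fitness"): the ecological
interaction between the populations is encoded purely in their metabolic
stoichiometries over the soluble substrates A-D (and O2 for the mixed
ecology).  Four presets are provided:

========================  ==================  ================================
preset                    net effect          metabolism
========================  ==================  ================================
neutralism                [0, 0, 0]           B1: A->D, B2: B->D, B3: C->D
competition               [-, -, -]           B1, B2, B3: A->B
commensalism              [0, +, +]           B1: A->B, B2: B->C, B3: C->D
commensalism_competition  environment-driven  commensal chain + shared O2
========================  ==================  ================================
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubstrateSpec",
    "PopulationSpec",
    "Cell",
    "CellState",
    "EcologyPreset",
    "SimulationConfig",
    "ConfigurationError",
    "IntegrityError",
    "build_ecology_preset",
    "generate_inoculum",
    "mg_per_l_to_molar",
    "m2_per_h_to_um2_per_h",
    "PRESET_NAMES",
    "DEFAULT_KINETICS",
]


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent configuration input."""


class IntegrityError(RuntimeError):
    """Raised when simulation state violates a structural invariant."""


# --- unit helpers ----------------------------------------------------------

#: litres per cubic micrometre
L_PER_UM3 = 1e-15
#: depth (um) of the pseudo-2D simulation domain used to convert per-node
#: molar amounts into concentrations
DOMAIN_DEPTH_UM = 1.0
#: molar mass of O2, g/mol
O2_MOLAR_MASS = 32.0


def mg_per_l_to_molar(mg_per_l: float, molar_mass: float = O2_MOLAR_MASS) -> float:
    """Convert a mass concentration in mg/L to mol/L."""
    return mg_per_l * 1e-3 / molar_mass


def m2_per_h_to_um2_per_h(d: float) -> float:
    """Convert a diffusivity from m^2/h to um^2/h (1 m^2 = 1e12 um^2)."""
    return d * 1e12


# --- default parameters ----------------------------------------------------

#: maximum cell mass at which division is triggered (mol biomass)
M_MAX_DEFAULT = 1.2e-14
#: minimum mass below which a cell inactivates (mol biomass); cells shrink
#: by at most ~half their linear size before dormancy
M_MIN_DEFAULT = 0.3 * M_MAX_DEFAULT
#: biomass density such that a cell of M_max has a 1 um radius (mol/um^3)
RHO_DEFAULT = M_MAX_DEFAULT / (4.0 / 3.0 * math.pi)

#: maximum specific growth rate, 1/h.  Cells then divide on the ~1 hour
#: timescale (ln 2 / mu_max), the natural fast-grower regime for this
#: model; maintenance is a fixed fraction of mu_max.
MU_MAX_DEFAULT = 0.7
#: maintenance, ~20% of mu_max: starved cells then shrink to dormancy on
#: the half-day timescale, within the maturation horizon of a run
B_MAX_DEFAULT = 0.15
#: half-saturation constants: 0.01 mM for the organic substrates A-D,
#: 0.5 mg/L for dissolved oxygen
KS_DEFAULT = 1e-5
KS_O2_DEFAULT = mg_per_l_to_molar(0.5)
#: growth yield, mol biomass per mol substrate
Y_XS_DEFAULT = 0.5

#: substrate diffusivities, um^2/h (3.6e-6 m^2/h for A-D; O2 set faster,
#: as expected for a small solute)
D_SOLUTE_DEFAULT = m2_per_h_to_um2_per_h(3.6e-6)
D_O2_DEFAULT = m2_per_h_to_um2_per_h(7.2e-6)

DEFAULT_KINETICS = {
    "mu_max": MU_MAX_DEFAULT,
    "b_max": B_MAX_DEFAULT,
    "K_S": KS_DEFAULT,
    "K_S_O2": KS_O2_DEFAULT,
    "Y_XS": Y_XS_DEFAULT,
    "M_max": M_MAX_DEFAULT,
    "M_min": M_MIN_DEFAULT,
    "rho": RHO_DEFAULT,
}

PRESET_NAMES = (
    "neutralism",
    "competition",
    "commensalism",
    "commensalism_competition",
)


# --- domain types ----------------------------------------------------------


@dataclass(frozen=True)
class SubstrateSpec:
    """One soluble component: identity, diffusivity and bulk concentration."""

    name: str
    diffusion_coefficient: float  # um^2/h
    bulk_concentration: float  # mol/L

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise ConfigurationError(
                f"substrate {self.name!r}: diffusion coefficient must be > 0"
            )
        if self.bulk_concentration < 0:
            raise ConfigurationError(
                f"substrate {self.name!r}: bulk concentration must be >= 0"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """Kinetic parameters and signed stoichiometry of one population.

    ``stoichiometry`` maps substrate name to a signed coefficient in mol
    substrate per mol biomass grown; negative values are consumption.
    ``K_S`` holds half-saturation constants for the consumed substrates and
    ``K_I`` inhibition constants (empty for all built-in presets).
    """

    name: str
    mu_max: float  # 1/h
    K_S: dict[str, float]  # mol/L
    K_I: dict[str, float] = field(default_factory=dict)  # mol/L
    b_max: float = B_MAX_DEFAULT  # 1/h
    Y_XS: float = Y_XS_DEFAULT  # mol biomass / mol substrate
    rho: float = RHO_DEFAULT  # mol biomass / um^3
    M_max: float = M_MAX_DEFAULT  # mol
    M_min: float = M_MIN_DEFAULT  # mol
    stoichiometry: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ConfigurationError(f"population {self.name!r}: mu_max must be > 0")
        if any(k <= 0 for k in self.K_S.values()):
            raise ConfigurationError(f"population {self.name!r}: all K_S must be > 0")
        if not (0 < self.M_min < self.M_max):
            raise ConfigurationError(
                f"population {self.name!r}: need 0 < M_min < M_max"
            )
        if self.rho <= 0 or self.Y_XS <= 0:
            raise ConfigurationError(
                f"population {self.name!r}: rho and Y_XS must be > 0"
            )

    @property
    def consumed(self) -> tuple[str, ...]:
        """Substrates this population takes up (negative coefficients)."""
        return tuple(s for s, c in self.stoichiometry.items() if c < 0)

    def kinetic_tuple(self) -> tuple:
        """Kinetics only, used to assert the equal-fitness invariant."""
        return (
            self.mu_max,
            self.b_max,
            self.Y_XS,
            self.rho,
            self.M_max,
            self.M_min,
            tuple(sorted(self.K_S.values())),
            tuple(sorted(self.K_I.values())),
        )


@dataclass
class Cell:
    """A single microbe: centre position, mass, identity and activity."""

    id: int
    population: str
    x: float  # um
    y: float  # um
    mass: float  # mol
    active: bool = True
    mu_current: float = 0.0  # 1/h, last computed actual growth rate

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ConfigurationError("cell mass must be >= 0")


@dataclass(frozen=True)
class EcologyPreset:
    """Substrates, populations and the net-effect signs of one ecology."""

    name: str
    substrates: tuple[SubstrateSpec, ...]
    populations: tuple[PopulationSpec, ...]
    interaction_signs: tuple[str, str, str]

    @property
    def substrate_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.substrates)

    def substrate(self, name: str) -> SubstrateSpec:
        for s in self.substrates:
            if s.name == name:
                return s
        raise KeyError(name)

    def bulk_concentrations(self) -> dict[str, float]:
        return {s.name: s.bulk_concentration for s in self.substrates}

    def stoichiometry_matrix(self) -> np.ndarray:
        """(n_populations, n_substrates) signed coefficient matrix."""
        mat = np.zeros((len(self.populations), len(self.substrates)))
        for i, pop in enumerate(self.populations):
            for j, sub in enumerate(self.substrates):
                mat[i, j] = pop.stoichiometry.get(sub.name, 0.0)
        return mat


@dataclass
class SimulationConfig:
    """Full description of one simulation experiment."""

    ecology: EcologyPreset
    grid: "object"  # reaction_diffusion.GridSpec
    scheduler: "object"  # scheduler.SchedulerSettings
    seed: int
    end_time: float  # h
    inoculum_diameter: float = 20.0  # um
    n_cells: int = 30
    detachment_radius: float | None = None  # um
    snapshot_interval: float = 2.0  # h
    stop_at_steady: bool = False
    stop_radius: float | None = None  # um, graceful stop before grid overflow
    store_fields: bool = False
    shoving: "object | None" = None  # mechanics.ShovingSettings

    def __post_init__(self) -> None:
        if self.inoculum_diameter <= 0:
            raise ConfigurationError("inoculum_diameter must be > 0")
        if self.end_time <= 0:
            raise ConfigurationError("end_time must be > 0")


class CellState:
    """Structure-of-arrays container for the whole cell population.

    This is the engine's working representation; :class:`Cell` objects are
    the per-cell view used by the scalar operations and tests.  All arrays
    share the same ordering.
    """

    __slots__ = ("ids", "pop", "x", "y", "mass", "active", "mu", "populations")

    def __init__(self, ids, pop, x, y, mass, active, mu, populations):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.pop = np.asarray(pop, dtype=np.int64)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.mass = np.asarray(mass, dtype=float)
        self.active = np.asarray(active, dtype=bool)
        self.mu = np.asarray(mu, dtype=float)
        self.populations = tuple(populations)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_cells(cls, cells: list[Cell], populations: tuple[str, ...]) -> "CellState":
        index = {name: i for i, name in enumerate(populations)}
        return cls(
            ids=[c.id for c in cells],
            pop=[index[c.population] for c in cells],
            x=[c.x for c in cells],
            y=[c.y for c in cells],
            mass=[c.mass for c in cells],
            active=[c.active for c in cells],
            mu=[c.mu_current for c in cells],
            populations=populations,
        )

    def to_cells(self) -> list[Cell]:
        return [
            Cell(
                id=int(self.ids[i]),
                population=self.populations[self.pop[i]],
                x=float(self.x[i]),
                y=float(self.y[i]),
                mass=float(self.mass[i]),
                active=bool(self.active[i]),
                mu_current=float(self.mu[i]),
            )
            for i in range(self.n)
        ]

    def copy(self) -> "CellState":
        return CellState(
            self.ids.copy(),
            self.pop.copy(),
            self.x.copy(),
            self.y.copy(),
            self.mass.copy(),
            self.active.copy(),
            self.mu.copy(),
            self.populations,
        )

    # -- views ---------------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def radii(self, rho_by_pop: np.ndarray) -> np.ndarray:
        """Cell radii in um given per-population biomass density."""
        vol = self.mass / rho_by_pop[self.pop]
        return np.cbrt(vol * 3.0 / (4.0 * math.pi))

    def select(self, mask: np.ndarray) -> "CellState":
        return CellState(
            self.ids[mask],
            self.pop[mask],
            self.x[mask],
            self.y[mask],
            self.mass[mask],
            self.active[mask],
            self.mu[mask],
            self.populations,
        )

    def to_frame(self, rho_by_pop: np.ndarray | None = None):
        import pandas as pd

        data = {
            "id": self.ids,
            "population": [self.populations[p] for p in self.pop],
            "x_um": self.x,
            "y_um": self.y,
            "mass_mol": self.mass,
            "mu_per_h": self.mu,
            "active": self.active,
        }
        if rho_by_pop is not None:
            data["radius_um"] = self.radii(rho_by_pop)
        return pd.DataFrame(data)


# --- ecology presets -------------------------------------------------------


def _population(name: str, stoich: dict[str, float], kin: dict) -> PopulationSpec:
    ks = {
        s: (kin["K_S_O2"] if s == "O2" else kin["K_S"])
        for s, c in stoich.items()
        if c < 0
    }
    return PopulationSpec(
        name=name,
        mu_max=kin["mu_max"],
        K_S=ks,
        b_max=kin["b_max"],
        Y_XS=kin["Y_XS"],
        rho=kin["rho"],
        M_max=kin["M_max"],
        M_min=kin["M_min"],
        stoichiometry=stoich,
    )


def _preset_stoichiometry(name: str, inv_y: float) -> list[dict[str, float]]:
    c, p = -inv_y, +inv_y
    if name == "neutralism":
        return [{"A": c, "D": p}, {"B": c, "D": p}, {"C": c, "D": p}]
    if name == "competition":
        return [{"A": c, "B": p}] * 3
    if name == "commensalism":
        return [{"A": c, "B": p}, {"B": c, "C": p}, {"C": c, "D": p}]
    if name == "commensalism_competition":
        return [
            {"A": c, "B": p, "O2": c},
            {"B": c, "C": p, "O2": c},
            {"C": c, "D": p, "O2": c},
        ]
    raise ConfigurationError(f"unknown ecology preset {name!r}")


_PRESET_SIGNS = {
    "neutralism": ("0", "0", "0"),
    "competition": ("-", "-", "-"),
    "commensalism": ("0", "+", "+"),
    # the mixed ecology's net effect depends on which substrate limits
    "commensalism_competition": ("~", "~", "~"),
}


def build_ecology_preset(
    name: str,
    bulk_concentrations: dict[str, float],
    kinetics: dict | None = None,
    diffusivities: dict[str, float] | None = None,
) -> EcologyPreset:
    """Build one of the four ecology presets.

    Parameters
    ----------
    name
        One of ``neutralism``, ``competition``, ``commensalism``,
        ``commensalism_competition``.
    bulk_concentrations
        Bulk (Dirichlet) concentrations in mol/L keyed by substrate name;
        substrates not listed default to zero (products).
    kinetics
        Overrides for :data:`DEFAULT_KINETICS` entries.
    diffusivities
        Per-substrate diffusivity overrides in um^2/h.
    """
    if name not in PRESET_NAMES:
        raise ConfigurationError(
            f"unknown ecology preset {name!r}; expected one of {PRESET_NAMES}"
        )
    if any(v < 0 for v in bulk_concentrations.values()):
        raise ConfigurationError("bulk concentrations must be >= 0")
    kin = dict(DEFAULT_KINETICS)
    if kinetics:
        kin.update(kinetics)

    substrate_names = ["A", "B", "C", "D"]
    if name == "commensalism_competition":
        substrate_names.append("O2")
    unknown = set(bulk_concentrations) - set(substrate_names)
    if unknown:
        raise ConfigurationError(
            f"substrates {sorted(unknown)} not part of preset {name!r}"
        )

    diff = {s: D_SOLUTE_DEFAULT for s in substrate_names}
    if "O2" in substrate_names:
        diff["O2"] = D_O2_DEFAULT
    if diffusivities:
        diff.update(diffusivities)

    substrates = tuple(
        SubstrateSpec(s, diff[s], bulk_concentrations.get(s, 0.0))
        for s in substrate_names
    )
    inv_y = 1.0 / kin["Y_XS"]
    populations = tuple(
        _population(f"B{i + 1}", stoich, kin)
        for i, stoich in enumerate(_preset_stoichiometry(name, inv_y))
    )
    return EcologyPreset(
        name=name,
        substrates=substrates,
        populations=populations,
        interaction_signs=_PRESET_SIGNS[name],
    )


# --- inoculum generator ----------------------------------------------------


def generate_inoculum(
    config: SimulationConfig,
    n_cells: int | None = None,
    seed: int | None = None,
    max_overlap_fraction: float = 0.05,
) -> list[Cell]:
    """Place a premature aggregate: cells randomly distributed in a disc.

    The three populations are represented in equal numbers; initial masses
    are uniform in [M_min, M_max); placement is uniform over the disc with
    rejection of pairs overlapping beyond the shoving threshold.  Fully
    deterministic for a given seed.
    """
    n = config.n_cells if n_cells is None else n_cells
    if n < 3 or n % 3 != 0:
        raise ConfigurationError("n_cells must be >= 3 and divisible by 3")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pops = config.ecology.populations
    radius_disc = config.inoculum_diameter / 2.0

    # quick feasibility check: disc must hold n cells of maximal size at the
    # accepted overlap without exceeding ~full packing
    r_max_cell = (pops[0].M_max / pops[0].rho * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    if n * math.pi * ((1 - max_overlap_fraction) * r_max_cell) ** 2 > math.pi * (
        radius_disc + r_max_cell
    ) ** 2:
        raise ConfigurationError(
            "inoculum disc too small to hold the requested number of cells"
        )

    labels = np.repeat(np.arange(3), n // 3)
    rng.shuffle(labels)
    masses = rng.uniform(pops[0].M_min, pops[0].M_max, size=n)
    radii = np.cbrt(masses / pops[0].rho * 3.0 / (4.0 * math.pi))

    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        placed = False
        for _ in range(2000):
            r = radius_disc * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            x, y = r * math.cos(th), r * math.sin(th)
            if i == 0:
                placed = True
            else:
                d2 = (xs[:i] - x) ** 2 + (ys[:i] - y) ** 2
                thresh = (1 - max_overlap_fraction) * (radii[:i] + radii[i])
                placed = bool(np.all(d2 >= thresh**2))
            if placed:
                xs[i], ys[i] = x, y
                break
        if not placed:
            raise ConfigurationError(
                "could not place inoculum cells without excess overlap"
            )

    return [
        Cell(
            id=i,
            population=pops[labels[i]].name,
            x=float(xs[i]),
            y=float(ys[i]),
            mass=float(masses[i]),
        )
        for i in range(n)
    ]
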