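"""Aggregate mechanics: hard-sphere shoving, geometry, shear detachment.

Growing and dividing microbes push their neighbours: whenever the space
shared by two cells exceeds the accepted overlap, both are displaced along
their centre line by half the deficit, and sweeps repeat until no pair
violates the rule (or an iteration cap is hit, which logs a warning and
returns the best state - crowded configurations relax fully on subsequent
steps).  Shoving changes positions only; masses, population identities and
activity states are untouched.

Shear forces are modelled as a radius cap: cells whose centres lie further
than the cap from the aggregate centre (the biomass-weighted centroid) are
detached and removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model_core import CellState, EcologyPreset, ConfigurationError

__all__ = [
    "ShovingSettings",
    "resolve_overlaps",
    "count_violating_pairs",
    "aggregate_centre",
    "aggregate_radius",
    "aggregate_centre_and_radius",
    "apply_detachment",
]

log = logging.getLogger(__name__)

#: golden-angle increment used to give coincident pairs a deterministic
#: separation direction
_GOLDEN_ANGLE = 2.399963229728653


@dataclass(frozen=True)
class ShovingSettings:
    """Overlap tolerance and iteration limits for the shoving pass."""

    max_overlap_fraction: float = 0.05
    max_iterations: int = 2000
    #: violating pairs are pushed slightly past the acceptance threshold;
    #: without this margin simultaneous pair updates settle into a limit
    #: cycle of marginal violations instead of converging
    overshoot: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_overlap_fraction < 1.0):
            raise ConfigurationError("max_overlap_fraction must be in [0, 1)")


def _violating_pairs(
    xy: np.ndarray, radii: np.ndarray, one_minus_f: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairs closer than (1-f)(r_i + r_j), their distances and thresholds."""
    if xy.shape[0] < 2:
        return np.empty((0, 2), dtype=np.int64), np.empty(0), np.empty(0)
    tree = cKDTree(xy)
    cutoff = one_minus_f * 2.0 * float(radii.max())
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2), np.empty(0), np.empty(0)
    # canonical ordering for determinism
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    diff = xy[pairs[:, 1]] - xy[pairs[:, 0]]
    dist = np.hypot(diff[:, 0], diff[:, 1])
    thresh = one_minus_f * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
    viol = dist < thresh * (1.0 - 1e-12)
    return pairs[viol], dist[viol], thresh[viol]


def count_violating_pairs(state: CellState, ecology: EcologyPreset, settings: ShovingSettings | None = None) -> int:
    """Exhaustive overlap check, the post-condition of the shoving pass."""
    settings = settings or ShovingSettings()
    rho = np.array([p.rho for p in ecology.populations])
    radii = state.radii(rho)
    xy = np.column_stack([state.x, state.y])
    pairs, _, _ = _violating_pairs(xy, radii, 1.0 - settings.max_overlap_fraction)
    return int(pairs.shape[0])


def resolve_overlaps(
    state: CellState,
    ecology: EcologyPreset,
    settings: ShovingSettings | None = None,
) -> CellState:
    """Iterative pairwise relaxation until no pair overlaps beyond the
    accepted fraction.  Returns the same state with updated positions;
    deterministic for a given input ordering.
    """
    settings = settings or ShovingSettings()
    one_minus_f = 1.0 - settings.max_overlap_fraction
    rho = np.array([p.rho for p in ecology.populations])
    radii = state.radii(rho)
    xy = np.column_stack([state.x, state.y])

    for _ in range(settings.max_iterations):
        pairs, dist, thresh = _violating_pairs(xy, radii, one_minus_f)
        if pairs.shape[0] == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        diff = xy[j] - xy[i]
        coincident = dist < 1e-9
        if np.any(coincident):
            ang = _GOLDEN_ANGLE * (i[coincident] + j[coincident]).astype(float)
            diff[coincident, 0] = np.cos(ang)
            diff[coincident, 1] = np.sin(ang)
            dist = np.where(coincident, 1.0, dist)
        unit = diff / dist[:, None]
        deficit = thresh * (1.0 + settings.overshoot) - np.where(coincident, 0.0, dist)
        push = 0.5 * deficit[:, None] * unit
        delta = np.zeros_like(xy)
        np.add.at(delta, j, push)
        np.add.at(delta, i, -push)
        xy += delta
    else:
        log.warning(
            "shoving iteration cap (%d) reached with %d violating pairs",
            settings.max_iterations,
            pairs.shape[0],
        )

    state.x = xy[:, 0].copy()
    state.y = xy[:, 1].copy()
    return state


# --- aggregate geometry -----------------------------------------------------


def aggregate_centre(state: CellState) -> tuple[float, float]:
    """Biomass-weighted centroid of all cells (um)."""
    if state.n == 0:
        raise ValueError("aggregate centre of an empty cell list is undefined")
    total = state.mass.sum()
    if total <= 0:
        return float(state.x.mean()), float(state.y.mean())
    return (
        float(np.dot(state.mass, state.x) / total),
        float(np.dot(state.mass, state.y) / total),
    )


def aggregate_radius(
    state: CellState,
    ecology: EcologyPreset,
    centre: tuple[float, float] | None = None,
) -> float:
    """Maximum centre distance plus cell radius over all cells (um)."""
    if state.n == 0:
        raise ValueError("aggregate radius of an empty cell list is undefined")
    if centre is None:
        centre = aggregate_centre(state)
    rho = np.array([p.rho for p in ecology.populations])
    radii = state.radii(rho)
    dist = np.hypot(state.x - centre[0], state.y - centre[1])
    return float(np.max(dist + radii))


def aggregate_centre_and_radius(
    state: CellState, ecology: EcologyPreset
) -> tuple[tuple[float, float], float]:
    centre = aggregate_centre(state)
    return centre, aggregate_radius(state, ecology, centre)


def apply_detachment(
    state: CellState,
    max_radius: float,
    centre: tuple[float, float] | None = None,
) -> CellState:
    """Remove cells whose centres lie strictly beyond the radius cap.

    The cap models shear force: everything further than ``max_radius`` from
    the aggregate centre detaches.  Idempotent; surviving cells untouched.
    """
    if max_radius <= 0:
        raise ConfigurationError("detachment max_radius must be > 0")
    if state.n == 0:
        return state
    if centre is None:
        centre = aggregate_centre(state)
    dist = np.hypot(state.x - centre[0], state.y - centre[1])
    keep = dist <= max_radius
    if np.all(keep):
        return state
    return state.select(keep)
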