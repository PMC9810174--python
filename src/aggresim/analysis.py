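"""Quantitative readouts of aggregate snapshots.

Implements the community statistics used to characterize the simulated
aggregates: relative abundances, fitness medians, colony sizes over
angular sections, the biological Thiele modulus and the eco-interaction
modulus, stratification indices (layering vs angular segregation) and the
statistical test suite (Welch, paired t, Pearson).

Colony size: sweeping angular bins about the aggregate centre, each bin is
labelled by the population of its radially outermost active cell; maximal
circularly contiguous same-label runs form colony sections.  A section's
perimeter is P_c = 2 pi <r> (theta / 360) with <r> the mean centre
distance of the labelling cells, and its relative size P_c / P_T with
P_T = 2 pi R the aggregate perimeter.

The biological Thiele modulus compares diffusion and reaction timescales,
phi_Bio = R q_S X / (D_S C_S); the eco-interaction modulus is the ratio of
the commensal substrate's modulus over the competitive one's,

    phi_EI = [(n_A q_A)/(D_A C_A)] / [(n_O2 q_O2)/(D_O2 C_O2)],

with n_i the relative abundance of consumers of substrate i.  phi_EI > 1
predicts a commensal (layered) environment, < 1 a competitive (columned)
one, and values in a near-unity band a mixed stratification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model_core import EcologyPreset

__all__ = [
    "ColonySection",
    "ThieleInputs",
    "StratificationIndices",
    "AnalysisError",
    "relative_abundance",
    "fitness_median",
    "colony_sections",
    "colony_size_summary",
    "thiele_modulus",
    "tau_diffusion",
    "tau_reaction_monod",
    "eco_interaction_modulus",
    "eco_interaction_modulus_from_snapshot",
    "classify_environment",
    "stratification_indices",
    "stats_suite",
    "abundance_fitness_correlation",
]


class AnalysisError(ValueError):
    """Raised when a statistic is undefined for the given snapshot."""


@dataclass(frozen=True)
class ColonySection:
    """One contiguous angular section occupied by a single population."""

    population: str
    theta: float  # degrees, (0, 360]
    mean_radius: float  # um
    P_c: float  # um
    relative_size: float  # P_c / P_T in (0, 1]


@dataclass(frozen=True)
class ThieleInputs:
    """Inputs of the biological Thiele modulus (consistent units)."""

    R: float  # aggregate radius, um
    q_S: float  # specific uptake rate, mol S / (mol X h)
    X: float  # biomass concentration, mol X / L
    D_S: float  # um^2/h
    C_S: float  # bulk concentration, mol/L
    Y_XS: float = 0.5
    n_i: float = 1.0  # relative abundance of consumers


@dataclass(frozen=True)
class StratificationIndices:
    layering_index: float
    segregation_index: float


# --- abundances and fitness -------------------------------------------------


def _counted(snapshot, active_only: bool):
    cells = snapshot.cells
    mask = cells.active if active_only else np.ones(cells.n, dtype=bool)
    return cells, mask


def relative_abundance(snapshot, active_only: bool = True) -> dict[str, float]:
    """Per-population fraction of counted (optionally active-only) cells."""
    cells, mask = _counted(snapshot, active_only)
    total = int(mask.sum())
    if total == 0:
        raise AnalysisError("no counted cells: relative abundance undefined")
    return {
        name: float(np.sum(mask & (cells.pop == i)) / total)
        for i, name in enumerate(cells.populations)
    }


def fitness_median(snapshot, population: str) -> float:
    """Median actual growth rate over a population's active cells (1/h)."""
    cells = snapshot.cells
    idx = cells.populations.index(population)
    sel = (cells.pop == idx) & cells.active
    if not sel.any():
        raise AnalysisError(f"population {population!r} has no active cells")
    return float(np.median(cells.mu[sel]))


# --- colony sections --------------------------------------------------------


def colony_sections(snapshot, angular_bin: float = 2.0) -> list[ColonySection]:
    """Angular colony sections labelled by the outermost active cell."""
    cells = snapshot.cells
    active = cells.active
    if not active.any():
        raise AnalysisError("no active cells: colony sections undefined")
    cx, cy = snapshot.centre
    dx, dy = cells.x[active] - cx, cells.y[active] - cy
    dist = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    pop = cells.pop[active]

    nbins = int(round(360.0 / angular_bin))
    bin_idx = np.minimum((ang / angular_bin).astype(int), nbins - 1)
    label = np.full(nbins, -1, dtype=int)
    label_r = np.zeros(nbins)
    for b in range(nbins):
        sel = bin_idx == b
        if not sel.any():
            continue
        k = np.argmax(dist[sel])
        label[b] = pop[sel][k]
        label_r[b] = dist[sel][k]

    # maximal circularly contiguous same-label runs; empty bins break runs
    runs: list[tuple[int, list[int]]] = []
    b = 0
    while b < nbins:
        if label[b] < 0:
            b += 1
            continue
        members = [b]
        while b + 1 < nbins and label[b + 1] == label[members[0]]:
            b += 1
            members.append(b)
        runs.append((label[members[0]], members))
        b += 1
    if len(runs) > 1 and label[0] >= 0 and label[-1] >= 0 and runs[0][0] == runs[-1][0] \
            and runs[0][1][0] == 0 and runs[-1][1][-1] == nbins - 1:
        last = runs.pop()
        runs[0] = (runs[0][0], last[1] + runs[0][1])

    R = snapshot.radius
    sections = []
    for pop_idx, members in runs:
        theta = len(members) * angular_bin
        mean_r = float(np.mean(label_r[members]))
        p_c = 2.0 * math.pi * mean_r * theta / 360.0
        sections.append(
            ColonySection(
                population=cells.populations[pop_idx],
                theta=theta,
                mean_radius=mean_r,
                P_c=p_c,
                relative_size=p_c / (2.0 * math.pi * R),
            )
        )
    return sections


def colony_size_summary(snapshot, angular_bin: float = 2.0) -> dict[str, float]:
    """Mean relative colony size per population over its sections."""
    sections = colony_sections(snapshot, angular_bin)
    out: dict[str, float] = {}
    for name in snapshot.cells.populations:
        sizes = [s.relative_size for s in sections if s.population == name]
        out[name] = float(np.mean(sizes)) if sizes else 0.0
    return out


# --- Thiele / eco-interaction moduli ---------------------------------------


def thiele_modulus(inputs: ThieleInputs) -> float:
    """phi_Bio = R q_S X / (D_S C_S), dimensionless."""
    denom = inputs.D_S * inputs.C_S
    if denom == 0:
        raise ZeroDivisionError("D_S * C_S must be non-zero")
    return inputs.R * inputs.q_S * inputs.X / denom


def tau_diffusion(R: float, D_S: float) -> float:
    """Characteristic diffusion time R^2 / D_S (h)."""
    return R * R / D_S


def tau_reaction_monod(
    Y_XS: float, mu_max: float, K_S: float, C_S: float, X: float
) -> float:
    """Characteristic Monod reaction time (Y/mu_max) (K_S + C_S) / X (h)."""
    return Y_XS / mu_max * (K_S + C_S) / X


def eco_interaction_modulus(
    n_A: float,
    q_A: float,
    D_A: float,
    C_A: float,
    n_O2: float,
    q_O2: float,
    D_O2: float,
    C_O2: float,
) -> float:
    """phi_EI = [(n_A q_A)/(D_A C_A)] / [(n_O2 q_O2)/(D_O2 C_O2)]."""
    if D_A * C_A == 0 or D_O2 * C_O2 == 0:
        raise ZeroDivisionError("diffusivity-concentration products must be non-zero")
    denom = n_O2 * q_O2 / (D_O2 * C_O2)
    if denom == 0:
        return math.inf
    return (n_A * q_A / (D_A * C_A)) / denom


def _bulk_specific_uptake(ecology: EcologyPreset, substrate: str) -> float:
    """Specific uptake rate of one substrate at bulk concentration,
    q = (1/Y) mu_max C/(K+C), for the populations consuming it."""
    sub = ecology.substrate(substrate)
    for pop in ecology.populations:
        if substrate in pop.consumed:
            ks = pop.K_S[substrate]
            monod = sub.bulk_concentration / (ks + sub.bulk_concentration)
            return abs(pop.stoichiometry[substrate]) * pop.mu_max * monod
    raise AnalysisError(f"no population consumes {substrate!r}")


def eco_interaction_modulus_from_snapshot(
    snapshot,
    ecology: EcologyPreset,
    commensal_substrate: str = "A",
    competitive_substrate: str = "O2",
) -> float:
    """phi_EI computed from a snapshot of the mixed ecology.

    n_i are the active-cell relative abundances of the consumers of each
    substrate; q_i the bulk-concentration specific uptake rates.
    """
    abundances = relative_abundance(snapshot, active_only=True)
    n_a = sum(
        abundances[p.name] for p in ecology.populations if commensal_substrate in p.consumed
    )
    n_o = sum(
        abundances[p.name]
        for p in ecology.populations
        if competitive_substrate in p.consumed
    )
    sub_a = ecology.substrate(commensal_substrate)
    sub_o = ecology.substrate(competitive_substrate)
    return eco_interaction_modulus(
        n_a,
        _bulk_specific_uptake(ecology, commensal_substrate),
        sub_a.diffusion_coefficient,
        sub_a.bulk_concentration,
        n_o,
        _bulk_specific_uptake(ecology, competitive_substrate),
        sub_o.diffusion_coefficient,
        sub_o.bulk_concentration,
    )


def classify_environment(phi_EI: float, near_threshold_band: float = 0.1) -> str:
    """Map phi_EI to the predicted stratification regime."""
    if phi_EI < 0:
        raise ValueError("phi_EI must be >= 0")
    if phi_EI > 1.0 + near_threshold_band:
        return "commensal/layered"
    if phi_EI < 1.0 - near_threshold_band:
        return "competitive/columned"
    return "mixed"


# --- stratification indices -------------------------------------------------


def stratification_indices(
    snapshot,
    angular_bin: float = 20.0,
    outer_shell_fraction: float = 0.25,
    min_abundance: float = 0.05,
) -> StratificationIndices:
    """Quantify layered vs columned organization of the active community.

    ``layering_index``: Spearman rank correlation between the commensal
    chain order (B1 < B2 < B3) and each population's median centre distance
    of active cells; -1 means each successor sits strictly below its
    predecessor (perfectly layered).

    ``segregation_index``: one minus the mean normalized Shannon entropy of
    the population composition over angular bins, restricted to the outer
    shell (outermost ``outer_shell_fraction`` of the aggregate radius);
    1 means each angular bin is pure (perfectly columned).

    Populations below ``min_abundance`` of the active community are left
    out of the layering ranking - the median position of a few remnant
    cells is noise, not stratification.  Fewer than two qualifying
    populations (competitive exclusion) leaves the indices undefined.
    """
    cells = snapshot.cells
    active = cells.active
    cx, cy = snapshot.centre
    dist = np.hypot(cells.x - cx, cells.y - cy)
    n_active = int(active.sum())

    order, med_r = [], []
    for i, _name in enumerate(cells.populations):
        sel = active & (cells.pop == i)
        if sel.any() and sel.sum() >= min_abundance * n_active:
            order.append(i)
            med_r.append(float(np.median(dist[sel])))
    if len(order) < 2:
        raise AnalysisError(
            "stratification indices need >= 2 meaningfully present populations"
        )
    if len(set(med_r)) == 1:
        layering = 0.0
    else:
        layering = float(sps.spearmanr(order, med_r).statistic)

    R = snapshot.radius
    shell = active & (dist >= (1.0 - outer_shell_fraction) * R)
    if not shell.any():
        raise AnalysisError("no active cells in the outer shell")
    ang = np.degrees(np.arctan2(cells.y[shell] - cy, cells.x[shell] - cx)) % 360.0
    pops = cells.pop[shell]
    nbins = int(round(360.0 / angular_bin))
    bin_idx = np.minimum((ang / angular_bin).astype(int), nbins - 1)
    k = len(cells.populations)
    entropies = []
    for b in range(nbins):
        sel = bin_idx == b
        if not sel.any():
            continue
        counts = np.bincount(pops[sel], minlength=k).astype(float)
        p = counts / counts.sum()
        nz = p > 0
        h = -np.sum(p[nz] * np.log(p[nz]))
        # Miller-Madow correction for finite per-bin counts, so a uniformly
        # mixed community scores ~0 segregation even in small bins
        h += (int(nz.sum()) - 1) / (2.0 * counts.sum())
        entropies.append(min(h / math.log(k), 1.0))
    segregation = 1.0 - float(np.mean(entropies))
    return StratificationIndices(layering, segregation)


# --- statistical test suite -------------------------------------------------


def abundance_fitness_correlation(df: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and p) between relative abundance and fitness median.

    ``df`` needs columns ``abundance`` and ``fitness_median``; one row per
    (population, replicate) pair.
    """
    a = df["abundance"].to_numpy(float)
    f = df["fitness_median"].to_numpy(float)
    if a.size < 3:
        raise AnalysisError("need at least 3 pairs for a correlation")
    if np.std(a) == 0 or np.std(f) == 0:
        return math.nan, math.nan
    r, p = sps.pearsonr(a, f)
    return float(r), float(p)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    if np.std(a) == 0 and np.std(b) == 0:
        return math.nan, math.nan, True
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), False


def stats_suite(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The statistical analyses over per-replicate summaries.

    Expects one row per (condition, replicate, population) with columns
    ``condition``, ``replicate``, ``population``, ``abundance``,
    ``fitness_median`` and optionally ``colony_rel_size``.

    Returns three tables:

    * ``welch`` - Welch's unequal-variance t-test of abundance (and colony
      size, when present) between every pair of conditions, per population;
    * ``paired_t`` - paired t-test of fitness medians between populations,
      pairing replicates within the same condition and simulation;
    * ``pearson`` - Pearson correlation between relative abundance and
      fitness median, per condition and pooled.

    Degenerate (zero-variance) comparisons are flagged rather than raised.
    """
    conditions = sorted(df["condition"].unique())
    populations = sorted(df["population"].unique())

    welch_rows = []
    metrics = ["abundance"] + (
        ["colony_rel_size"] if "colony_rel_size" in df.columns else []
    )
    for metric in metrics:
        for popn in populations:
            for i, ca in enumerate(conditions):
                for cb in conditions[i + 1 :]:
                    a = df.query("condition == @ca and population == @popn")[metric]
                    b = df.query("condition == @cb and population == @popn")[metric]
                    if len(a) < 2 or len(b) < 2:
                        continue
                    t, p, degen = _welch(a.to_numpy(float), b.to_numpy(float))
                    welch_rows.append(
                        dict(metric=metric, population=popn, condition_a=ca,
                             condition_b=cb, t=t, p=p, degenerate=degen)
                    )

    paired_rows = []
    wide = df.pivot_table(
        index=["condition", "replicate"], columns="population",
        values="fitness_median",
    )
    for i, pa in enumerate(populations):
        for pb in populations[i + 1 :]:
            sub = wide[[pa, pb]].dropna()
            if len(sub) < 2:
                continue
            diff = sub[pa] - sub[pb]
            if np.std(diff) == 0:
                t, p, degen = math.nan, math.nan, True
            else:
                t, p = sps.ttest_rel(sub[pa], sub[pb])
                t, p, degen = float(t), float(p), False
            paired_rows.append(
                dict(population_a=pa, population_b=pb, mean_difference=float(diff.mean()),
                     t=t, p=p, n=len(sub), degenerate=degen)
            )

    pearson_rows = []
    for cond in conditions + ["pooled"]:
        sub = df if cond == "pooled" else df[df["condition"] == cond]
        if len(sub) < 3:
            continue
        r, p = abundance_fitness_correlation(sub)
        pearson_rows.append(dict(condition=cond, r=r, p=p, n=len(sub)))

    return {
        "welch": pd.DataFrame(welch_rows),
        "paired_t": pd.DataFrame(paired_rows),
        "pearson": pd.DataFrame(pearson_rows),
    }
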