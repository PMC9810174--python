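"""Community statistics: abundances, fitness, colony sections, moduli,
stratification indices and the statistical test suite."""

import math

import numpy as np
import pandas as pd
import pytest

from aggresim import analysis
from aggresim.analysis import (
    AnalysisError,
    ThieleInputs,
    classify_environment,
    colony_sections,
    eco_interaction_modulus,
    fitness_median,
    relative_abundance,
    stats_suite,
    stratification_indices,
    tau_diffusion,
    tau_reaction_monod,
    thiele_modulus,
)
from aggresim.experiments import make_fixture
from aggresim.model_core import CellState
from aggresim.scheduler import AggregateSnapshot


def snapshot_from(x, y, pop, active=None, mu=None, radius=None):
    n = len(x)
    cells = CellState(
        ids=np.arange(n),
        pop=pop,
        x=x,
        y=y,
        mass=np.full(n, 6e-15),
        active=np.ones(n, dtype=bool) if active is None else np.asarray(active),
        mu=np.zeros(n) if mu is None else np.asarray(mu, dtype=float),
        populations=("B1", "B2", "B3"),
    )
    r = radius if radius is not None else float(np.hypot(cells.x, cells.y).max()) + 1.0
    return AggregateSnapshot(
        time=0.0, cells=cells, bulk={}, centre=(0.0, 0.0), radius=r, summary={}
    )


class TestAbundanceAndFitness:
    def test_equal_counts(self):
        snap = snapshot_from(np.zeros(30), np.zeros(30), np.arange(30) % 3)
        ab = relative_abundance(snap)
        assert ab == {"B1": pytest.approx(1 / 3), "B2": pytest.approx(1 / 3), "B3": pytest.approx(1 / 3)}

    def test_active_only_excludes_dormant(self):
        pop = [0] * 15 + [1] * 10 + [2] * 10
        active = [True] * 10 + [False] * 5 + [True] * 20
        snap = snapshot_from(np.zeros(35), np.zeros(35), pop, active=active)
        ab = relative_abundance(snap, active_only=True)
        assert ab["B1"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        snap = snapshot_from(np.zeros(50), np.zeros(50), rng.integers(0, 3, 50))
        assert sum(relative_abundance(snap).values()) == pytest.approx(1.0)

    def test_no_counted_cells_errors(self):
        snap = snapshot_from(np.zeros(3), np.zeros(3), [0, 1, 2], active=[False] * 3)
        with pytest.raises(AnalysisError):
            relative_abundance(snap, active_only=True)

    @pytest.mark.parametrize(
        "mu, expected", [([0.2, 0.2, 0.2], 0.2), ([0.1, 0.2, 0.3], 0.2)]
    )
    def test_fitness_median(self, mu, expected):
        snap = snapshot_from(np.zeros(3), np.zeros(3), [0, 0, 0], mu=mu)
        assert fitness_median(snap, "B1") == pytest.approx(expected)

    def test_fitness_median_robust_to_outlier(self):
        snap = snapshot_from(np.zeros(3), np.zeros(3), [0, 0, 0], mu=[0.1, 0.2, 0.3])
        doubled = snapshot_from(np.zeros(3), np.zeros(3), [0, 0, 0], mu=[0.1, 0.2, 0.6])
        assert fitness_median(snap, "B1") == fitness_median(doubled, "B1")

    def test_fitness_median_needs_active_cells(self):
        snap = snapshot_from(np.zeros(3), np.zeros(3), [0, 1, 2], active=[False, True, True])
        with pytest.raises(AnalysisError):
            fitness_median(snap, "B1")


class TestColonySections:
    def test_single_population_full_circle(self):
        ang = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        snap = snapshot_from(8 * np.cos(ang), 8 * np.sin(ang), np.zeros(720, int), radius=10.0)
        sections = colony_sections(snap)
        assert len(sections) == 1
        s = sections[0]
        assert s.theta == pytest.approx(360.0)
        assert s.relative_size == pytest.approx(s.mean_radius / 10.0)

    def test_quarter_arc_relative_size(self):
        # B1 occupies a 90 degree arc at the aggregate radius; B2 the rest
        ang1 = np.radians(np.arange(0, 90, 1.0) + 0.5)
        ang2 = np.radians(np.arange(90, 360, 1.0) + 0.5)
        x = np.concatenate([10 * np.cos(ang1), 10 * np.cos(ang2)])
        y = np.concatenate([10 * np.sin(ang1), 10 * np.sin(ang2)])
        pop = np.array([0] * len(ang1) + [1] * len(ang2))
        snap = snapshot_from(x, y, pop, radius=10.0)
        b1 = [s for s in colony_sections(snap, angular_bin=2.0) if s.population == "B1"]
        assert len(b1) == 1
        assert b1[0].theta == pytest.approx(90.0, abs=2.0)
        assert b1[0].relative_size == pytest.approx(0.25, abs=0.01)

    def test_three_equal_sectors(self):
        snap = make_fixture("sectors", n=3000, seed=1, radius=10.0)
        sections = colony_sections(snap, angular_bin=2.0)
        assert len(sections) == 3
        assert {s.population for s in sections} == {"B1", "B2", "B3"}
        total_theta = sum(s.theta for s in sections)
        assert total_theta <= 360.0 + 1e-9
        assert sum(s.relative_size for s in sections) <= 1.0 + 1e-9

    def test_empty_bins_split_runs(self):
        # two same-population arcs separated by empty space stay two sections
        ang1 = np.radians(np.arange(0, 60, 1.0))
        ang2 = np.radians(np.arange(180, 240, 1.0))
        x = np.concatenate([9 * np.cos(ang1), 9 * np.cos(ang2)])
        y = np.concatenate([9 * np.sin(ang1), 9 * np.sin(ang2)])
        snap = snapshot_from(x, y, np.zeros(len(x), int), radius=10.0)
        assert len(colony_sections(snap)) == 2


class TestModuli:
    def test_unit_thiele(self):
        assert thiele_modulus(ThieleInputs(R=1, q_S=1, X=1, D_S=1, C_S=1)) == 1.0

    def test_thiele_linear_in_radius(self):
        base = ThieleInputs(R=5, q_S=2, X=3, D_S=7, C_S=11)
        doubled = ThieleInputs(R=10, q_S=2, X=3, D_S=7, C_S=11)
        assert thiele_modulus(doubled) == pytest.approx(2 * thiele_modulus(base))

    def test_characteristic_times(self):
        assert tau_diffusion(10.0, 100.0) == pytest.approx(1.0)
        assert tau_reaction_monod(0.5, 0.5, 1e-5, 1e-5, 1.0) == pytest.approx(2e-5)

    def test_eco_modulus_symmetric_arguments(self):
        assert eco_interaction_modulus(0.5, 2, 3, 4, 0.5, 2, 3, 4) == pytest.approx(1.0)

    def test_eco_modulus_zero_consumers(self):
        assert eco_interaction_modulus(0.0, 1, 1, 1, 1, 1, 1, 1) == 0.0

    def test_eco_modulus_hand_value(self):
        assert eco_interaction_modulus(0.5, 2, 1, 1, 1, 1, 2, 1) == pytest.approx(2.0)

    def test_eco_modulus_homogeneous_in_uptake(self):
        a = eco_interaction_modulus(0.4, 1.0, 1, 1e-4, 1.0, 2.0, 2, 3e-4)
        b = eco_interaction_modulus(0.4, 7.0, 1, 1e-4, 1.0, 14.0, 2, 3e-4)
        assert a == pytest.approx(b)

    def test_infinite_when_no_competitor(self):
        assert math.isinf(eco_interaction_modulus(1, 1, 1, 1, 0.0, 1, 1, 1))

    @pytest.mark.parametrize(
        "phi, expected",
        [
            (1.51, "commensal/layered"),
            (0.65, "competitive/columned"),
            (1.07, "mixed"),
        ],
    )
    def test_classification(self, phi, expected):
        assert classify_environment(phi, near_threshold_band=0.1) == expected


class TestStratification:
    def test_concentric_rings_perfectly_layered(self):
        snap = make_fixture("concentric", ring_radii=(3.0, 6.0, 9.0))
        idx = stratification_indices(snap)
        assert idx.layering_index == pytest.approx(-1.0)

    def test_sector_segregation_approaches_one_with_finer_bins(self):
        snap = make_fixture("sectors", n=3000, seed=2)
        seg = [
            stratification_indices(snap, angular_bin=b).segregation_index
            for b in (60.0, 20.0, 5.0)
        ]
        assert seg[0] <= seg[1] <= seg[2] + 1e-12
        assert seg[2] > 0.9

    def test_random_labels_near_zero(self):
        lays, segs = [], []
        for seed in range(30):
            snap = make_fixture("random", n=400, seed=seed)
            idx = stratification_indices(snap)
            lays.append(idx.layering_index)
            segs.append(idx.segregation_index)
        assert abs(np.mean(lays)) < 0.25
        assert abs(np.mean(segs)) < 0.1

    def test_single_population_undefined(self):
        snap = snapshot_from(np.arange(5.0), np.zeros(5), np.zeros(5, int))
        with pytest.raises(AnalysisError):
            stratification_indices(snap)


class TestStatsSuite:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["condition", "replicate", "population", "abundance", "fitness_median"]
        )

    def test_identical_samples_flagged_degenerate(self):
        rows = [
            (c, r, p, 0.33, 0.1)
            for c in ("x", "y")
            for r in range(3)
            for p in ("B1", "B2", "B3")
        ]
        out = stats_suite(self._frame(rows))
        assert out["welch"]["degenerate"].all()
        assert out["paired_t"]["degenerate"].all()

    def test_paired_t_detects_constant_offset(self):
        rows = []
        rng = np.random.default_rng(1)
        for r in range(6):
            base = 0.2 + rng.normal(0, 0.01)
            rows.append(("x", r, "B1", 0.4, base + 0.1))
            rows.append(("x", r, "B2", 0.3, base))
            rows.append(("x", r, "B3", 0.3, base - 0.05))
        out = stats_suite(self._frame(rows))
        row = out["paired_t"].query("population_a == 'B1' and population_b == 'B2'").iloc[0]
        assert row["mean_difference"] == pytest.approx(0.1)
        assert row["p"] < 1e-6

    def test_collinear_pairs_give_unit_correlation(self):
        rows = [
            ("x", r, p, a, 0.5 * a)
            for r in range(3)
            for p, a in zip(("B1", "B2", "B3"), (0.5, 0.3, 0.2))
        ]
        out = stats_suite(self._frame(rows))
        pooled = out["pearson"].query("condition == 'pooled'").iloc[0]
        assert pooled["r"] == pytest.approx(1.0)

    def test_welch_separates_shifted_conditions(self):
        rng = np.random.default_rng(2)
        rows = []
        for c, shift in (("lo", 0.0), ("hi", 0.2)):
            for r in range(5):
                for p in ("B1", "B2", "B3"):
                    rows.append((c, r, p, 0.3 + shift + rng.normal(0, 0.01), 0.1))
        out = stats_suite(self._frame(rows))
        assert (out["welch"]["p"] < 0.001).all()
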