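"""Nonparametric characterization statistics."""

import numpy as np
import pandas as pd
import pytest

from gaitstrat.core_data import ClusterAssignment, TemporospatialRecord
from gaitstrat.stats import (
    CHI2_VARIABLES,
    KW_VARIABLES,
    bonferroni,
    characterize_clusters,
    chi_squared,
    kruskal_wallis,
    posthoc_pairwise,
    side_medians,
    spearman,
)
from gaitstrat.synthetic_data import CohortConfig, generate_cohort
from .conftest import make_cycle


class TestKruskalWallis:
    def test_identical_groups_no_evidence(self):
        r = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_worked_rank_example(self):
        # three tie-free groups occupying rank blocks {1-3},{4-6},{7-9}:
        # H = 12/(9*10) * 3 * ((2-5)^2 + 0 + (8-5)^2) = 7.2
        r = kruskal_wallis([[1, 2, 3], [10, 11, 12], [20, 21, 22]])
        assert r.statistic == pytest.approx(7.2)
        assert r.df == 2

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestPosthoc:
    def test_six_groups_fifteen_pairs(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(i, 1, size=8) for i in range(6)]
        ph = posthoc_pairwise(groups)
        assert len(ph) == 15

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.02, 15) == pytest.approx(0.30)
        assert bonferroni(0.2, 15) == 1.0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, size=10) for _ in range(4)]
        for method in ("dunn_bonferroni", "mannwhitney_bonferroni"):
            ph = posthoc_pairwise(groups, method=method)
            assert (ph["adjusted_p"] >= ph["p_value"] - 1e-12).all()
            assert (ph["adjusted_p"] <= 1.0).all()

    def test_separated_groups_significant(self):
        ph = posthoc_pairwise([[1, 2, 3, 4, 5], [101, 102, 103, 104, 105]])
        assert ph.loc[0, "adjusted_p"] < 0.05


class TestChiSquared:
    def test_independence_gives_zero(self):
        rows = np.array([10, 20])
        cols = np.array([0.3, 0.7])
        table = np.outer(rows, cols)
        r = chi_squared(table)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_perfect_association_2x2(self):
        r = chi_squared([[10, 0], [0, 10]])
        assert r.statistic == pytest.approx(20.0)
        assert r.df == 1

    def test_df_for_2x6(self):
        rng = np.random.default_rng(2)
        r = chi_squared(rng.integers(1, 20, size=(2, 6)))
        assert r.df == 5

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [3, 4]])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = np.array([0.1, 0.5, 1.2, 3.0, 7.7])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        x = np.arange(10.0)
        r = spearman(x, -x)
        assert r.rho == pytest.approx(-1.0)
        assert r.df == 8

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r1 = spearman(x, y).rho
        r2 = spearman(np.exp(x), y**3 + 5 * y).rho
        assert r1 == pytest.approx(r2)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_type_one_error_calibrated(self):
        """KW at alpha=0.05 rejects ~5% of null samples (2000 sims)."""
        rng = np.random.default_rng(4)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = [rng.standard_normal(10) for _ in range(3)]
            if kruskal_wallis(groups).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestSideMedians:
    def _setup(self):
        cycles, ts = [], []
        speeds = [1.0, 1.1, 1.2, 1.2, 1.3]
        for i, v in enumerate(speeds, start=1):
            cycles.append(make_cycle(seed=i, cycle_index=i))
            ts.append(TemporospatialRecord("S01", "left", i, v, 0.6, 0.1))
        assignment = ClusterAssignment(
            labels={c.pattern_id: 0 for c in cycles}, names={0: "blue"})
        return cycles, ts, assignment

    def test_median_of_five(self):
        cycles, ts, assignment = self._setup()
        t = side_medians(cycles, ts, assignment)
        assert len(t) == 1
        assert t.loc[0, "walking_speed"] == pytest.approx(1.2)
        assert t.loc[0, "cluster"] == "blue"

    def test_even_count_midpoint(self):
        cycles, ts, assignment = self._setup()
        t = side_medians(cycles[:2], ts[:2], assignment)
        assert t.loc[0, "walking_speed"] == pytest.approx(1.05)

    def test_single_cycle_passthrough(self):
        cycles, ts, assignment = self._setup()
        t = side_medians(cycles[:1], ts[:1], assignment)
        assert t.loc[0, "walking_speed"] == pytest.approx(1.0)

    def test_missing_record_names_cycle(self):
        cycles, ts, assignment = self._setup()
        with pytest.raises(ValueError, match="S01_left_c5"):
            side_medians(cycles, ts[:4], assignment)


@pytest.fixture(scope="module")
def cohort_report():
    cohort = generate_cohort(CohortConfig(n_subjects=12, n_controls=0, seed=3))
    isci = cohort.isci_cycles
    planted = dict(zip(cohort.planted.pattern_id, cohort.planted.archetype))
    arch_names = sorted({planted[c.pattern_id] for c in isci})
    label_of = {a: i for i, a in enumerate(arch_names)}
    assignment = ClusterAssignment(
        labels={c.pattern_id: label_of[planted[c.pattern_id]] for c in isci},
        names={i: a for a, i in label_of.items()},
    )
    side_table = side_medians(isci, cohort.temporospatial, assignment)
    return characterize_clusters(side_table, cohort.subjects)


class TestCharacterizeClusters:

    def test_every_variable_tested_once(self, cohort_report):
        assert set(cohort_report.tests) == set(KW_VARIABLES) | set(
            CHI2_VARIABLES)

    def test_posthoc_pair_count(self, cohort_report):
        g = len(cohort_report.counts)
        expected_pairs = g * (g - 1) // 2
        for var in KW_VARIABLES:
            assert len(cohort_report.posthoc[var]) == expected_pairs

    def test_counts_report_sides_and_cycles(self, cohort_report):
        c = cohort_report.counts
        assert (c["n_cycles"] == 5 * c["n_sides"]).all()

    def test_null_clusters_rarely_significant(self):
        """Labels split at random within one archetype: adjusted p > 0.05."""
        rng = np.random.default_rng(5)
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            cohort = generate_cohort(CohortConfig(
                n_subjects=12, n_controls=0, seed=seed,
                side_archetypes=tuple([("green", "green")] * 12),
            ))
            isci = cohort.isci_cycles
            sides = sorted({(c.subject_id, c.side) for c in isci})
            half = set(map(tuple, rng.permutation(sides)[:len(sides) // 2]))
            assignment = ClusterAssignment(
                labels={c.pattern_id: int((c.subject_id, c.side) in half)
                        for c in isci},
                names={0: "a", 1: "b"},
            )
            side_table = side_medians(isci, cohort.temporospatial, assignment)
            report = characterize_clusters(side_table, cohort.subjects)
            ok = all(
                (report.posthoc[v]["adjusted_p"] > 0.05).all()
                for v in ("walking_speed", "step_length", "step_width")
            )
            hits += ok
        assert hits >= 0.9 * n_runs
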