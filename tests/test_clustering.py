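"""Ward-like linkage against classical Ward and direct inertia bookkeeping."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from gaitstrat.clustering import (
    cut_dendrogram,
    cut_k,
    hac_wardlike,
    side_assignments,
    suggest_threshold,
)
from gaitstrat.core_data import ClusterAssignment, DissimilarityMatrix
from gaitstrat.dtw import pairwise_matrix
from gaitstrat.preprocess import fit_normalization
from gaitstrat.synthetic_data import CohortConfig, generate_cohort
from .conftest import make_cycle


def matrix_from_points(points):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    d = squareform(pdist(points))
    return DissimilarityMatrix(
        pattern_ids=tuple(f"p{i}" for i in range(len(points))), values=d
    )


def greedy_inertia_oracle(d2):
    """Direct pseudo-inertia bookkeeping: I(C) = (1/n) sum_{i<j in C} d2.

    Greedily merges the pair whose union minimizes the inertia increase,
    recomputing I from scratch at every step.  Returns the merge heights.
    """
    n = d2.shape[0]

    def inertia(c):
        return sum(d2[i, j] for i, j in itertools.combinations(sorted(c), 2)) / len(c)

    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            u = clusters[a] | clusters[b]
            dh = inertia(u) - inertia(clusters[a]) - inertia(clusters[b])
            if best is None or dh < best[0] - 1e-12:
                best = (dh, a, b)
        dh, a, b = best
        heights.append(dh)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return np.array(heights)


class TestHacWardlike:
    def test_two_leaves_height_half_squared(self):
        m = DissimilarityMatrix(
            pattern_ids=("a", "b"),
            values=np.array([[0.0, 3.0], [3.0, 0.0]]),
        )
        d = hac_wardlike(m)
        assert d.merges[0][2] == pytest.approx(4.5)  # 3**2 / 2

    def test_three_point_line_worked_example(self):
        # 1-D points {0, 1, 10}: first merge {0,1} at (1/2)*1 = 0.5; the
        # second merge's inertia increase is I({0,1,10}) - I({0,1})
        # = (1 + 100 + 81)/3 - 1/2 = 361/6.
        d = hac_wardlike(matrix_from_points([0.0, 1.0, 10.0]))
        heights = [m[2] for m in d.merges]
        assert heights[0] == pytest.approx(0.5)
        assert heights[1] == pytest.approx(361.0 / 6.0)
        assert d.merges[0][:2] == (0, 1)

    @pytest.mark.parametrize("n,dim,seed", [(10, 2, 0), (30, 3, 1), (50, 5, 2)])
    def test_matches_classical_ward_on_euclidean_clouds(self, n, dim, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, dim))
        d = hac_wardlike(matrix_from_points(pts))
        ours = np.array([m[2] for m in d.merges])
        scipy_h = linkage(pts, method="ward")[:, 2]
        # scipy ward heights h relate to inertia increases as h**2 / 2
        np.testing.assert_allclose(ours, scipy_h**2 / 2.0, atol=1e-9)

    @pytest.mark.parametrize("n,seed", [(6, 0), (9, 1), (12, 2)])
    def test_matches_direct_inertia_bookkeeping(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, 3))
        d2 = squareform(pdist(pts)) ** 2
        d = hac_wardlike(matrix_from_points(pts))
        ours = np.array([m[2] for m in d.merges])
        np.testing.assert_allclose(ours, greedy_inertia_oracle(d2), rtol=1e-9)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((25, 4))
        h = hac_wardlike(matrix_from_points(pts)).heights
        assert np.all(np.diff(h) >= -1e-12)


@pytest.fixture(scope="module")
def line_dendrogram():
    return hac_wardlike(matrix_from_points([0.0, 1.0, 10.0]))


class TestCuts:
    def test_threshold_above_root_single_cluster(self, line_dendrogram):
        a = cut_dendrogram(line_dendrogram, 1e9)
        assert a.n_clusters == 1

    def test_threshold_below_first_merge_all_singletons(self, line_dendrogram):
        a = cut_dendrogram(line_dendrogram, 0.1)
        assert a.n_clusters == 3

    def test_threshold_ten_separates_far_point(self, line_dendrogram):
        a = cut_dendrogram(line_dendrogram, 10.0)
        assert a.n_clusters == 2
        assert a.labels["p0"] == a.labels["p1"] != a.labels["p2"]

    def test_cut_k_extremes(self, line_dendrogram):
        assert cut_k(line_dendrogram, 1).n_clusters == 1
        assert cut_k(line_dendrogram, 3).n_clusters == 3

    def test_cut_k_out_of_range(self, line_dendrogram):
        with pytest.raises(ValueError):
            cut_k(line_dendrogram, 0)
        with pytest.raises(ValueError):
            cut_k(line_dendrogram, 4)

    def test_labels_size_ranked(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate([
            rng.normal(0, 0.1, size=(8, 2)),
            rng.normal(5, 0.1, size=(3, 2)),
        ])
        a = cut_k(hac_wardlike(matrix_from_points(pts)), 2)
        assert len(a.members(0)) == 8  # label 0 = largest cluster
        assert len(a.members(1)) == 3
        assert a.names[0] == "blue"

    def test_suggest_threshold_recovers_gap(self):
        rng = np.random.default_rng(5)
        pts = np.concatenate([
            rng.normal(0, 0.1, size=(6, 2)),
            rng.normal(8, 0.1, size=(6, 2)),
        ])
        d = hac_wardlike(matrix_from_points(pts))
        a = cut_dendrogram(d, suggest_threshold(d))
        assert a.n_clusters == 2


class TestSideAssignments:
    def _assignment(self, labels):
        return ClusterAssignment(
            labels=labels, names={l: f"c{l}" for l in set(labels.values())}
        )

    def test_consistent_side(self):
        cycles = [make_cycle(seed=i, cycle_index=i + 1) for i in range(5)]
        a = self._assignment({c.pattern_id: 0 for c in cycles})
        t = side_assignments(a, cycles)
        assert len(t) == 1
        assert bool(t.loc[0, "consistent"]) is True
        assert t.loc[0, "label"] == 0

    def test_mixed_side_gets_modal_label(self):
        cycles = [make_cycle(seed=i, cycle_index=i + 1) for i in range(5)]
        labels = {c.pattern_id: (0 if i < 3 else 1)
                  for i, c in enumerate(cycles)}
        t = side_assignments(self._assignment(labels), cycles)
        assert t.loc[0, "label"] == 0
        assert bool(t.loc[0, "consistent"]) is False

    def test_unlabeled_cycle_rejected(self):
        cycles = [make_cycle(seed=0)]
        with pytest.raises(ValueError):
            side_assignments(self._assignment({"nope": 0}), cycles)


class TestPlantedRecovery:
    def test_archetype_recovery_over_seeds(self):
        """Default-condition cohorts: cut at 6 recovers planted archetypes."""
        aris = []
        for seed in range(20):
            cohort = generate_cohort(CohortConfig(seed=seed, n_controls=0))
            isci = cohort.isci_cycles
            m = pairwise_matrix(isci, fit_normalization(isci))
            a = cut_k(hac_wardlike(m), 6)
            planted = dict(zip(cohort.planted.pattern_id,
                               cohort.planted.archetype))
            ids = list(a.labels)
            aris.append(adjusted_rand_score(
                [planted[i] for i in ids], [a.labels[i] for i in ids]))
        assert min(aris) >= 0.9
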