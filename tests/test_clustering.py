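import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score

from p53pool.clustering import (DEFAULT_ASSIGNMENT_RULES, UNASSIGNABLE,
                                AssignmentRule, ClusterFeatureSummary,
                                assign_to_clusters, assignment_percentages,
                                calinski_harabasz, cluster_weights,
                                hierarchical_cluster, pairwise_dissimilarity,
                                peak_based_mean, select_cluster_count)
from p53pool.synthetic import (LOW_NOISE, GeneratorConfig, default_pool,
                               generate_calibration_cells)
from p53pool.trajectories import Trajectory, features_dataframe

GRID = 0.25 * np.arange(97)


def waveform_cells(n_groups=3, per_group=12, noise=0.02, seed=0):
    """Planted waveform groups differing in pulse period and phase."""
    rng = np.random.default_rng(seed)
    cells, labels = [], []
    for g in range(n_groups):
        period = 4.0 + 1.5 * g
        phase = 1.0 + 0.8 * g
        for i in range(per_group):
            y = 0.5 + 0.5 * np.sin(2 * np.pi * (GRID - phase) / period)
            y = y + noise * rng.standard_normal(GRID.size)
            cells.append(Trajectory(f"g{g}_c{i}", GRID.copy(), y))
            labels.append(g)
    return cells, np.array(labels)


class TestDissimilarity:
    def test_identical_trajectories_zero_distance(self):
        cells, _ = waveform_cells(1, 2, noise=0.0)
        D = pairwise_dissimilarity(cells)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_zero_diagonal(self):
        cells, _ = waveform_cells(2, 3)
        D = pairwise_dissimilarity(cells)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_hand_computed_three_sample_distance(self):
        a = Trajectory("a", [0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        b = Trajectory("b", [0.0, 1.0, 2.0], [1.0, 0.0, 1.0])
        D = pairwise_dissimilarity([a, b], sigma=0)
        assert D[0, 1] == pytest.approx(np.sqrt(3.0))

    def test_feature_method_runs_and_is_symmetric(self):
        cells, _ = waveform_cells(2, 4)
        D = pairwise_dissimilarity(cells, method="features")
        np.testing.assert_allclose(D, D.T, atol=1e-9)


class TestHierarchical:
    def one_d_matrix(self, points):
        return squareform(pdist(np.asarray(points, float)[:, None]))

    def test_two_planted_groups_recovered(self):
        D = self.one_d_matrix([0.0, 0.1, 10.0, 10.1])
        labels = hierarchical_cluster(D, 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n_minus_one_merges_closest_pair(self):
        D = self.one_d_matrix([0.0, 5.0, 5.2, 11.0])
        labels = hierarchical_cluster(D, 3)
        assert labels[1] == labels[2]
        assert len(set(labels)) == 3

    def test_duplicated_cell_co_clusters(self):
        D = self.one_d_matrix([0.0, 0.0, 3.0, 7.0, 7.5])
        labels = hierarchical_cluster(D, 3)
        assert labels[0] == labels[1]

    def test_invalid_k_rejected(self):
        D = self.one_d_matrix([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            hierarchical_cluster(D, 3)


class TestCalinskiHarabasz:
    def test_hand_computed_toy(self):
        """{0,1} vs {10,11}: B = 100, W = 1 so CH = (100/1)/(1/2) = 200."""
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([1, 1, 2, 2])
        assert calinski_harabasz(X, labels) == pytest.approx(200.0)

    def test_agrees_with_sklearn_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        labels = rng.integers(1, 4, size=40)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-9)

    def test_identical_centroids_score_zero(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        assert calinski_harabasz(X, np.array([1, 1, 2, 2])) == pytest.approx(0.0)

    def test_degenerate_within_scatter_rejected(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            calinski_harabasz(X, np.array([1, 1, 2, 2]))

    def test_planted_labels_beat_random_labels(self):
        cells, labels = waveform_cells(3, 10)
        from p53pool.clustering import trajectory_matrix

        X = trajectory_matrix(cells)
        rng = np.random.default_rng(0)
        random_scores = [calinski_harabasz(X, rng.permutation(labels))
                         for _ in range(5)]
        assert calinski_harabasz(X, labels) > 5 * max(random_scores)


class TestSelectClusterCount:
    def test_three_planted_waveform_groups(self):
        cells, _ = waveform_cells(3, 12, seed=1)
        k_star, labels, scores = select_cluster_count(cells, range(2, 9))
        assert k_star == 3
        assert len(set(labels)) == 3

    def test_single_candidate_range(self):
        cells, _ = waveform_cells(2, 6)
        k_star, _, _ = select_cluster_count(cells, [2])
        assert k_star == 2

    def test_empty_range_rejected(self):
        cells, _ = waveform_cells(2, 4)
        with pytest.raises(ValueError):
            select_cluster_count(cells, [])

    def test_recovery_rate_on_seeded_low_noise_pools(self):
        """Planted cluster count is recovered in >= 90% of 20 seeds."""
        pool = default_pool(3)
        hits = 0
        for seed in range(20):
            cfg = GeneratorConfig(pool=pool, n_cells=60, seed=seed, **LOW_NOISE)
            cells, _ = generate_calibration_cells(cfg)
            k_star, _, _ = select_cluster_count(cells, range(2, 9))
            hits += k_star == 3
        assert hits >= 18


class TestPeakBasedMean:
    def test_single_trajectory_returns_own_extrema(self, ref_params):
        from p53pool.ode import observe_p53, simulate
        from p53pool.trajectories import detect_extrema, smooth

        res = simulate(ref_params, t_span=(0.0, 24.0))
        t, y = observe_p53(res)
        tr = Trajectory("a", GRID + 0.5, np.interp(GRID + 0.5, t, y))
        mean = peak_based_mean([tr])
        seq = detect_extrema(smooth(tr))
        np.testing.assert_allclose(mean.peak_times,
                                   [e.time for e in seq.maxima][: mean.n_peaks])

    def test_two_member_arithmetic_means(self):
        from p53pool.trajectories import Extremum, ExtremaSequence

        seqs = [ExtremaSequence("a", [Extremum("max", 2.0, 10.0)]),
                ExtremaSequence("b", [Extremum("max", 4.0, 20.0)])]
        trajs = [Trajectory(s.cell_id, np.array([0.0, 1.0]), np.array([1.0, 2.0]))
                 for s in seqs]
        mean = peak_based_mean(trajs, seqs)
        assert mean.peak_times[0] == pytest.approx(3.0)
        assert mean.peak_values[0] == pytest.approx(15.0)
        assert mean.initial_value == pytest.approx(1.0)

    def test_coverage_rule_drops_rare_peak_indices(self):
        from p53pool.trajectories import Extremum, ExtremaSequence

        def seq(cell, n):
            ex = []
            for i in range(n):
                ex.append(Extremum("max", 2.0 + 5.0 * i, 10.0))
                ex.append(Extremum("min", 4.5 + 5.0 * i, 2.0))
            return ExtremaSequence(cell, ex)

        seqs = [seq("a", 3), seq("b", 5)]
        trajs = [Trajectory(s.cell_id, np.array([0.0, 1.0]), np.array([1.0, 1.0]))
                 for s in seqs]
        assert peak_based_mean(trajs, seqs, coverage=0.5).n_peaks == 5
        assert peak_based_mean(trajs, seqs, coverage=0.75).n_peaks == 3

    def test_no_peaks_anywhere_rejected(self):
        flat = [Trajectory("a", GRID, np.ones(GRID.size))]
        with pytest.raises(ValueError, match="no member"):
            peak_based_mean(flat)


@pytest.fixture(scope="module")
def calibration():
    pool = default_pool(3)
    cfg = GeneratorConfig(pool=pool, n_cells=60, seed=7, **LOW_NOISE)
    cells, truth = generate_calibration_cells(cfg)
    labels = truth.subpopulation + 1
    feats = features_dataframe(cells)
    summary = ClusterFeatureSummary.from_features(
        feats, labels, [c.cell_id for c in cells])
    return cells, labels, summary


class TestAssignment:
    def test_self_assignment_reproduces_labels(self, calibration):
        cells, labels, summary = calibration
        out = assign_to_clusters(cells, summary, rules=None)
        agreement = np.mean(out["cluster"].to_numpy() == labels)
        assert agreement >= 0.95

    def test_delayed_copy_assigned_to_source_cluster(self, calibration):
        cells, labels, summary = calibration
        src = cells[0]
        delayed = Trajectory("delayed", src.times, np.interp(
            src.times - 1.0, src.times, src.values))
        out = assign_to_clusters([delayed], summary)
        assert out.loc[0, "cluster"] == labels[0]

    def test_flat_trajectory_unassignable(self, calibration):
        _, _, summary = calibration
        flat = Trajectory("flat", GRID, np.ones(GRID.size))
        out = assign_to_clusters([flat], summary)
        assert out.loc[0, "cluster"] == UNASSIGNABLE

    def test_percentages_and_weights_normalise(self, calibration):
        cells, _, summary = calibration
        out = assign_to_clusters(cells, summary)
        pct = assignment_percentages(out)
        assert pct.sum() == pytest.approx(100.0)
        w = cluster_weights(out["cluster"].to_numpy())
        assert sum(w.values()) == pytest.approx(1.0)

    def test_rule_count_is_nine(self):
        assert len(DEFAULT_ASSIGNMENT_RULES) == 9
        assert all(isinstance(r, AssignmentRule) for r in DEFAULT_ASSIGNMENT_RULES)
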