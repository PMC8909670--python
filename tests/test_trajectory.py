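import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from methyltraj import (ClusterGraph, GMMModel, InputError,
                        UnsupportedTopologyError, assign_pseudotime,
                        choose_start_cluster, fit_embedding, fit_principal_curve,
                        fit_trajectory, initial_path, minimum_spanning_tree,
                        predict_pseudotime, select_gmm, embed)
from methyltraj.preprocess import build_reference, quantile_normalize, \
    site_age_correlation, select_sites
from methyltraj.trajectory import _project_onto_polyline


def brute_force_mst_weight(centers):
    """Minimum spanning-tree weight by enumerating all labeled trees
    (Pruefer sequences, Cayley's formula)."""
    k = len(centers)
    dist = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
    best = np.inf
    for seq in itertools.product(range(k), repeat=k - 2):
        edges = pruefer_to_edges(list(seq), k)
        best = min(best, sum(dist[i, j] for i, j in edges))
    return best


def pruefer_to_edges(seq, k):
    degree = [1] * k
    for v in seq:
        degree[v] += 1
    edges = []
    for v in seq:
        for leaf in range(k):
            if degree[leaf] == 1:
                edges.append((leaf, v))
                degree[leaf] -= 1
                degree[v] -= 1
                break
    last = [v for v in range(k) if degree[v] == 1]
    edges.append((last[0], last[1]))
    return edges


def make_gmm(means, assignments_coords=None):
    """Minimal mixture model with identity covariances at given means."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    k, d = means.shape
    return GMMModel(k=k, family="spherical-free",
                    weights=np.full(k, 1.0 / k), means=means,
                    covariances=np.repeat(np.eye(d)[None], k, axis=0),
                    log_likelihood=0.0, n_params=0)


class TestMst:
    def test_three_collinear_centers(self):
        centers = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        edges = minimum_spanning_tree(centers)
        assert sorted(edges) == [(0, 1), (1, 2)]
        weight = sum(np.linalg.norm(centers[i] - centers[j]) for i, j in edges)
        assert weight == pytest.approx(3.0)

    def test_single_center(self):
        assert minimum_spanning_tree(np.array([[1.0, 2.0]])) == []

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(5):
            centers = rng.uniform(0, 10, (5, 2))
            edges = minimum_spanning_tree(centers)
            weight = sum(np.linalg.norm(centers[i] - centers[j])
                         for i, j in edges)
            assert weight == pytest.approx(brute_force_mst_weight(centers),
                                           abs=1e-9)


class TestStartCluster:
    def test_youngest_cluster_wins(self):
        gmm = make_gmm([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]])
        coords = np.array([[0.1, 0], [4.9, 0], [10.2, 0]])
        ages = np.array([5.0, 40.0, 70.0])
        assert choose_start_cluster(gmm, coords, ages) == 0
        assert choose_start_cluster(gmm, coords[::-1], ages[::-1]) == 0

    def test_single_cluster(self):
        gmm = make_gmm([[0.0, 0.0]])
        assert choose_start_cluster(gmm, np.zeros((3, 2)), np.array([1, 2, 3])) == 0

    def test_tie_broken_by_smaller_index(self):
        gmm = make_gmm([[0.0, 0.0], [10.0, 0.0]])
        coords = np.array([[0.0, 0], [10.0, 0]])
        assert choose_start_cluster(gmm, coords, np.array([30.0, 30.0])) == 0


class TestInitialPath:
    def test_path_tree(self):
        centers = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        graph = ClusterGraph(centers=centers, edges=[(0, 1), (1, 2)],
                             start_cluster=0)
        assert initial_path(graph) == [0, 1, 2]

    def test_single_cluster(self):
        graph = ClusterGraph(centers=np.array([[0.0, 0]]), edges=[])
        assert initial_path(graph) == [0]

    def test_star_tree_rejected(self):
        centers = np.array([[0.0, 0], [1.0, 0], [0, 1.0], [-1.0, 0]])
        graph = ClusterGraph(centers=centers,
                             edges=[(0, 1), (0, 2), (0, 3)], start_cluster=1)
        with pytest.raises(UnsupportedTopologyError):
            initial_path(graph)

    def test_interior_start_rejected(self):
        centers = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        graph = ClusterGraph(centers=centers, edges=[(0, 1), (1, 2)],
                             start_cluster=1)
        with pytest.raises(UnsupportedTopologyError):
            initial_path(graph)


class TestPrincipalCurve:
    def test_line_is_fixed_point(self, rng):
        t = np.sort(rng.uniform(0, 10, 100))
        coords = np.column_stack([t, 2 * t])
        path = np.array([[0.0, 0.0], [10.0, 20.0]])
        curve = fit_principal_curve(coords, path)
        _, d2 = _project_onto_polyline(coords, curve.control_points)
        assert d2.sum() <= 1e-10

    def test_quarter_circle_improves_on_initial_path(self, rng):
        theta = rng.uniform(0, np.pi / 2, 300)
        coords = np.column_stack([np.cos(theta), np.sin(theta)])
        coords += rng.normal(0, 0.02, coords.shape)
        path = np.array([[1.0, 0.0], [np.sqrt(0.5), np.sqrt(0.5)], [0.0, 1.0]])
        curve = fit_principal_curve(coords, path)
        assert curve.mse_history[-1] <= curve.mse_history[0] + 1e-12

    def test_max_iter_zero_returns_initial_path(self):
        coords = np.array([[0.0, 0], [1.0, 1], [2.0, 0]])
        path = np.array([[0.0, 0.0], [2.0, 0.0]])
        curve = fit_principal_curve(coords, path, max_iter=0)
        assert curve.total_length == pytest.approx(2.0)
        np.testing.assert_allclose(curve.control_points[[0, -1]], path)

    def test_identical_points_rejected(self):
        with pytest.raises(InputError):
            fit_principal_curve(np.ones((5, 2)), np.array([[0.0, 0], [1.0, 0]]))


class TestAssignPseudotime:
    def _curve(self):
        path = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        return fit_principal_curve(np.array([[0.0, 0], [1, 0], [1, 1.0]]),
                                   path, max_iter=0)

    def test_first_control_point_is_zero(self):
        curve = self._curve()
        assert assign_pseudotime(curve, np.array([[0.0, 0.0]]))[0] == 0.0

    def test_beyond_end_clamps_to_total_length(self):
        curve = self._curve()
        t = assign_pseudotime(curve, np.array([[1.0, 5.0]]))[0]
        assert t == pytest.approx(curve.total_length)

    def test_matches_dense_sampling_oracle(self, rng):
        curve = self._curve()
        # dense-sampling projection oracle at 1e5 points along the polyline
        grid = np.linspace(0, curve.total_length, 100_000)
        pts = np.empty((grid.size, 2))
        cum = curve.cumulative_arc_length
        for dim in range(2):
            pts[:, dim] = np.interp(grid, cum, curve.control_points[:, dim])
        for point in rng.uniform(-1, 2, (20, 2)):
            dense_t = grid[np.argmin(((pts - point) ** 2).sum(axis=1))]
            t = assign_pseudotime(curve, point.reshape(1, -1))[0]
            assert abs(t - dense_t) <= 1e-3 * curve.total_length


class TestRigidMotion:
    def test_rotation_translation_invariance(self, rng):
        coords = np.column_stack([np.sort(rng.uniform(0, 10, 200)),
                                  rng.normal(0, 0.3, 200)])
        path = np.array([[0.0, 0.0], [10.0, 0.0]])
        curve = fit_principal_curve(coords, path)
        t0 = assign_pseudotime(curve, coords)

        angle = 0.7
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        shift = np.array([3.0, -2.0])
        coords_r = coords @ R.T + shift
        curve_r = fit_principal_curve(coords_r, path @ R.T + shift)
        t1 = assign_pseudotime(curve_r, coords_r)
        np.testing.assert_allclose(t0, t1, atol=1e-8)


class TestPredictPseudotime:
    def _model(self, cohort):
        train = cohort["train"]
        ref = build_reference(train)
        train_n = quantile_normalize(train, ref)
        sel = select_sites(train_n.probe_ids, site_age_correlation(train_n), 0.4)
        train_s = train_n.select_probes(sel.probe_ids)
        embedding = fit_embedding(train_s.betas, 2, train_s.ages)
        coords = embed(embedding, train_s.betas)
        gmm = select_gmm(coords, (1, 2, 3, 4), seed=0)
        model = fit_trajectory(coords, gmm, train_s.ages, embedding,
                               train_s.probe_ids)
        return model, ref, sel

    def test_training_data_reproduces_fit_assignment(self, small_cohort):
        model, ref, sel = self._model(small_cohort)
        train_s = quantile_normalize(small_cohort["train"], ref).select_probes(
            sel.probe_ids)
        coords = embed(model.embedding, train_s.betas)
        np.testing.assert_allclose(predict_pseudotime(model, train_s),
                                   assign_pseudotime(model.curve, coords),
                                   atol=1e-12)

    def test_duplicated_samples_get_identical_values(self, small_cohort):
        model, ref, sel = self._model(small_cohort)
        test_s = quantile_normalize(small_cohort["test"], ref).select_probes(
            sel.probe_ids)
        dup = test_s.select_samples([0, 0, 1])
        pt = predict_pseudotime(model, dup)
        assert pt[0] == pt[1]

    def test_site_mismatch_names_missing_probes(self, small_cohort):
        model, ref, sel = self._model(small_cohort)
        test_s = quantile_normalize(small_cohort["test"], ref).select_probes(
            sel.probe_ids[:-1])
        with pytest.raises(InputError, match=sel.probe_ids[-1]):
            predict_pseudotime(model, test_s)

    def test_test_pseudotime_tracks_true_state(self, small_cohort):
        model, ref, sel = self._model(small_cohort)
        test_s = quantile_normalize(small_cohort["test"], ref).select_probes(
            sel.probe_ids)
        pt = predict_pseudotime(model, test_s)
        truth = small_cohort["truth"].states_for(test_s)
        assert np.corrcoef(pt, truth)[0, 1] >= 0.95

    def test_pseudotime_range_and_cluster_order(self, small_cohort):
        model, ref, sel = self._model(small_cohort)
        train_s = quantile_normalize(small_cohort["train"], ref).select_probes(
            sel.probe_ids)
        coords = embed(model.embedding, train_s.betas)
        pt = predict_pseudotime(model, train_s)
        assert (pt >= 0).all() and (pt <= model.curve.total_length).all()
        labels = model.gmm.predict(coords)
        start = model.graph.start_cluster
        end = initial_path(model.graph)[-1]
        if start != end and (labels == start).any() and (labels == end).any():
            assert (np.median(pt[labels == start])
                    < np.median(pt[labels == end]))

    def test_monotone_in_state_on_clean_data(self, clean_cohort):
        model, ref, sel = self._model(clean_cohort)
        train_s = quantile_normalize(clean_cohort["train"], ref).select_probes(
            sel.probe_ids)
        pt = predict_pseudotime(model, train_s)
        truth = clean_cohort["truth"].states_for(train_s)
        rho = spearmanr(pt, truth).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)
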