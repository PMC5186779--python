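"""Distance + similarity prediction model: scores, edge selection and the
gamma scan."""

import numpy as np
import pytest

from brainpred.model import (
    LinkPrediction,
    euclidean_distance_matrix,
    gamma_grid,
    gamma_scan,
    prediction_scores,
    select_edges,
)
from brainpred.similarity import compute_similarity
from brainpred.types import (
    BrainNetwork,
    NodeCoordinates,
    SimilarityMatrix,
    edge_count_for_sparsity,
)
from brainpred.evaluation import prediction_power
from brainpred.synthetic import generate_coordinates, generate_spatial_modular_network
from brainpred.types import SyntheticConfig

from conftest import random_network


def coords_of(points, labels=None):
    points = np.asarray(points, dtype=float)
    labels = labels or [f"n{i}" for i in range(len(points))]
    return NodeCoordinates(labels=labels, positions=points)


class TestDistance:
    def test_pythagorean_triples(self):
        c = coords_of([[0, 0, 0], [3, 4, 0], [3, 4, 12]])
        d = euclidean_distance_matrix(c).d
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 2] == pytest.approx(13.0)
        assert d[1, 2] == pytest.approx(12.0)

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 50, (20, 3))
        d = euclidean_distance_matrix(coords_of(pts)).d
        for i in range(20):
            for j in range(20):
                expected = np.sqrt(((pts[i] - pts[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_coincident_centroids_rejected(self):
        c = coords_of([[0, 0, 0], [0, 0, 0], [1, 1, 1]], ["a", "b", "c"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            euclidean_distance_matrix(c)


def sim_of(matrix, labels, name="CN"):
    return SimilarityMatrix(labels=labels, index_name=name, s=matrix)


class TestScores:
    def test_gamma_zero_is_pure_distance(self):
        """s^0 = 1 for every s, including 0, so the gamma=0 ranking equals
        the 1/d ranking."""
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (8, 3))
        c = coords_of(pts)
        dist = euclidean_distance_matrix(c)
        s = np.zeros((8, 8))
        s[0, 1] = s[1, 0] = 5.0  # some nonzero, some zero similarities
        scores = prediction_scores(dist, sim_of(s, c.labels), 0.0)
        iu, ju = np.triu_indices(8, k=1)
        got = np.argsort(scores.p[iu, ju])
        expected = np.argsort(1.0 / dist.d[iu, ju])
        np.testing.assert_array_equal(got, expected)

    def test_zero_similarity_zero_score_in_penalty_mode(self):
        c = coords_of([[0, 0, 0], [10, 0, 0]])
        dist = euclidean_distance_matrix(c)
        s = np.zeros((2, 2))
        scores = prediction_scores(dist, sim_of(s, c.labels), 1.5)
        assert scores.p[0, 1] == 0.0

    @pytest.mark.parametrize("mode", ["penalty", "literal"])
    def test_matches_scalar_loop_oracle(self, mode):
        rng = np.random.default_rng(2)
        n = 12
        pts = rng.uniform(0, 80, (n, 3))
        c = coords_of(pts)
        dist = euclidean_distance_matrix(c)
        s = rng.uniform(0, 4, (n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        gamma = 1.7
        scores = prediction_scores(dist, sim_of(s, c.labels), gamma, mode)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                expected = (
                    s[i, j] ** gamma / dist.d[i, j]
                    if mode == "penalty"
                    else dist.d[i, j] * s[i, j] ** gamma
                )
                assert scores.p[i, j] == pytest.approx(expected, rel=1e-12)

    def test_distance_rescaling_preserves_ranking_in_penalty_mode(self):
        rng = np.random.default_rng(3)
        n = 10
        pts = rng.uniform(0, 60, (n, 3))
        c1 = coords_of(pts)
        c2 = coords_of(pts * 3.7)
        s = rng.uniform(0, 2, (n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        p1 = prediction_scores(euclidean_distance_matrix(c1), sim_of(s, c1.labels), 1.2)
        p2 = prediction_scores(euclidean_distance_matrix(c2), sim_of(s, c2.labels), 1.2)
        iu, ju = np.triu_indices(n, k=1)
        np.testing.assert_array_equal(
            np.argsort(p1.p[iu, ju]), np.argsort(p2.p[iu, ju])
        )

    def test_label_mismatch_rejected(self):
        c = coords_of([[0, 0, 0], [1, 0, 0]], ["a", "b"])
        dist = euclidean_distance_matrix(c)
        s = sim_of(np.zeros((2, 2)), ["x", "y"])
        with pytest.raises(ValueError, match="labels"):
            prediction_scores(dist, s, 1.0)


class TestSelectEdges:
    def test_top_m_distinct(self):
        labels = ["a", "b", "c", "d"]
        p = np.zeros((4, 4))
        p[0, 1] = p[1, 0] = 9
        p[2, 3] = p[3, 2] = 8
        p[0, 2] = p[2, 0] = 1
        from brainpred.types import ScoreMatrix

        scores = ScoreMatrix(labels, p, 1.0, "CN", "penalty")
        net = select_edges(scores, 2)
        assert net.edge_set() == {(0, 1), (2, 3)}

    def test_all_equal_reproducible(self):
        from brainpred.types import ScoreMatrix

        labels = [f"n{i}" for i in range(10)]
        p = np.ones((10, 10))
        np.fill_diagonal(p, 0)
        scores = ScoreMatrix(labels, p, 0.0, "PA", "penalty")
        e1 = select_edges(scores, 5, tie_seed=3).edge_set()
        e2 = select_edges(scores, 5, tie_seed=3).edge_set()
        assert e1 == e2 and len(e1) == 5

    def test_out_of_range_m_rejected(self):
        from brainpred.types import ScoreMatrix

        labels = ["a", "b", "c"]
        scores = ScoreMatrix(labels, np.zeros((3, 3)), 0.0, "CN", "penalty")
        with pytest.raises(ValueError):
            select_edges(scores, 0)
        with pytest.raises(ValueError):
            select_edges(scores, 4)


class TestGammaScan:
    def test_trace_has_31_points(self):
        net = random_network(20, 0.25, 0)
        rng = np.random.default_rng(0)
        c = coords_of(rng.uniform(0, 100, (20, 3)), net.labels)
        _, _, trace = gamma_scan(net, euclidean_distance_matrix(c), "CN")
        assert len(trace) == 31
        assert len(gamma_grid()) == 31
        np.testing.assert_allclose(np.diff(gamma_grid()), 0.1)

    def test_distance_built_network_perfect_at_gamma_zero(self):
        """When the real edges are exactly the m shortest pairs, the pure
        distance model recovers them all and attains the maximal power."""
        rng = np.random.default_rng(4)
        n, m = 15, 20
        pts = rng.uniform(0, 100, (n, 3))
        c = coords_of(pts)
        dist = euclidean_distance_matrix(c)
        iu, ju = np.triu_indices(n, k=1)
        order = np.argsort(dist.d[iu, ju])[:m]
        a = np.zeros((n, n), dtype=np.int8)
        a[iu[order], ju[order]] = 1
        a |= a.T
        real = BrainNetwork(labels=c.labels, adjacency=a)
        best_gamma, predicted, trace = gamma_scan(real, dist, "CN")
        assert trace[0] == pytest.approx(max(trace))
        n_pairs = n * (n - 1) // 2
        assert max(trace) == pytest.approx(10 * np.log10(n_pairs / m))

    def test_scan_dominates_gamma_zero(self):
        """The scanned best criterion is at least the pure-distance value,
        on networks with planted triadic structure."""
        cfg = SyntheticConfig(
            n_regions=40, n_modules=4, sparsity=0.2, within_module_boost=30, seed=5
        )
        coords = generate_coordinates(40, 5)
        truth = generate_spatial_modular_network(coords, cfg)
        dist = euclidean_distance_matrix(coords)
        _, _, trace = gamma_scan(truth.network, dist, "CN")
        assert max(trace) >= trace[0]

    def test_predicted_network_passes_invariants(self):
        cfg = SyntheticConfig(n_regions=90, sparsity=0.05, seed=6)
        coords = generate_coordinates(90, 6)
        truth = generate_spatial_modular_network(coords, cfg)
        dist = euclidean_distance_matrix(coords)
        _, predicted, _ = gamma_scan(truth.network, dist, "RA")
        assert predicted.n_edges == edge_count_for_sparsity(90, 0.05) == 200
        a = predicted.adjacency
        assert np.array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)

    def test_self_prediction_bounds_all_predictions(self):
        """No prediction beats predicting the real edge set itself."""
        net = random_network(25, 0.2, 7)
        rng = np.random.default_rng(7)
        c = coords_of(rng.uniform(0, 100, (25, 3)), net.labels)
        dist = euclidean_distance_matrix(c)
        bound = prediction_power(net, net)
        for index in ("CN", "PA", "RA"):
            _, predicted, trace = gamma_scan(net, dist, index)
            assert max(trace) <= bound + 1e-12

    def test_unknown_criterion_rejected(self):
        net = random_network(10, 0.3, 8)
        rng = np.random.default_rng(8)
        c = coords_of(rng.uniform(0, 50, (10, 3)), net.labels)
        with pytest.raises(ValueError, match="criterion"):
            gamma_scan(net, euclidean_distance_matrix(c), "CN", criterion="bogus")


class TestLinkPredictionObject:
    def test_fit_summary_and_results(self):
        cfg = SyntheticConfig(n_regions=40, n_modules=4, sparsity=0.15, seed=9)
        coords = generate_coordinates(40, 9)
        truth = generate_spatial_modular_network(coords, cfg)
        model = LinkPrediction(truth.network, coords, "CN")
        res = model.fit()
        assert res.predicted.n_edges == truth.network.n_edges
        assert 0 <= res.recovered_fraction <= 1
        text = res.summary()
        assert "CN" in text and "prediction power" in text
        assert res.best_gamma == pytest.approx(
            model.grid[int(np.argmax(res.trace))]
        )

    def test_energy_criterion_runs(self):
        cfg = SyntheticConfig(n_regions=25, n_modules=3, sparsity=0.25, seed=10)
        coords = generate_coordinates(25, 10, mirror=False)
        truth = generate_spatial_modular_network(coords, cfg)
        model = LinkPrediction(
            truth.network, coords, "CN", criterion="energy", grid=np.array([0.0, 1.0])
        )
        res = model.fit()
        assert len(res.trace) == 2
        assert np.all(np.isfinite(res.trace))
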