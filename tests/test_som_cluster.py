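import numpy as np
import pytest
from scipy.spatial.distance import cdist

from somdbn import som_cluster as som


def two_blobs(rng, n=100, dim=4, gap=8.0):
    return np.vstack(
        [rng.normal(0, 1, (n, dim)), rng.normal(gap, 1, (n, dim))]
    )


class TestInitGrid:
    def test_seed_determinism_and_unit_count(self, rng):
        X = rng.normal(size=(30, 3))
        a = som.init_grid(2, 3, 3, X, seed=5)
        b = som.init_grid(2, 3, 3, X, seed=5)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.n_units == 6

    def test_constant_input_constant_weights(self):
        X = np.full((10, 2), 7.0)
        grid = som.init_grid(2, 2, 2, X, seed=1)
        np.testing.assert_allclose(grid.weights, 7.0)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            som.init_grid(2, 2, 2, np.empty((0, 2)), seed=1)


class TestFindBMU:
    def test_exact_weight_match(self, rng):
        grid = som.init_grid(2, 3, 4, rng.normal(size=(20, 4)), seed=2)
        assert som.find_bmu(grid, grid.weights[4]) == 4

    def test_matches_exhaustive_scan(self, rng):
        """Oracle: brute-force distance scan via scipy cdist."""
        grid = som.init_grid(3, 3, 5, rng.normal(size=(50, 5)), seed=3)
        queries = rng.normal(size=(500, 5))
        oracle = cdist(queries, grid.weights).argmin(axis=1)
        ours = [som.find_bmu(grid, q) for q in queries]
        np.testing.assert_array_equal(ours, oracle)

    def test_tie_goes_to_lowest_index(self):
        weights = np.zeros((4, 2))
        grid = som.SOMGrid(rows=2, cols=2, weights=weights)
        assert som.find_bmu(grid, np.array([1.0, 1.0])) == 0

    def test_non_finite_query_errors(self, rng):
        grid = som.init_grid(1, 2, 2, rng.normal(size=(5, 2)), seed=1)
        with pytest.raises(ValueError):
            som.find_bmu(grid, np.array([np.nan, 0.0]))


class TestNeighborhood:
    def test_bmu_weight_is_one(self, rng):
        grid = som.init_grid(2, 3, 2, rng.normal(size=(5, 2)), seed=1)
        assert som.neighborhood_weight(grid, 3, 3, 1.0) == 1.0

    def test_adjacent_closed_form(self, rng):
        grid = som.init_grid(2, 3, 2, rng.normal(size=(5, 2)), seed=1)
        # units 0 and 1 sit one lattice step apart
        assert som.neighborhood_weight(grid, 0, 1, 1.0) == pytest.approx(
            np.exp(-0.5)
        )

    def test_small_radius_vanishes(self, rng):
        grid = som.init_grid(2, 3, 2, rng.normal(size=(5, 2)), seed=1)
        assert som.neighborhood_weight(grid, 0, 1, 1e-3) < 1e-100


class TestTrain:
    def test_single_repeated_record_fixed_point(self):
        x = np.array([2.0, -1.0, 0.5])
        X = np.tile(x, (30, 1)) + 1e-9
        grid = som.init_grid(2, 2, 3, X + np.random.default_rng(0).normal(0, 1, X.shape), seed=4)
        trained = som.train(grid, X, epochs=300)
        assert np.abs(trained.weights - x[None, :]).max() < 1e-3

    def test_zero_learning_rate_no_change(self, rng):
        X = rng.normal(size=(20, 3))
        grid = som.init_grid(2, 2, 3, X, seed=1)
        frozen = som.SOMGrid(
            rows=2, cols=2, weights=grid.weights, lr_initial=0.0, lr_final=0.0
        )
        trained = som.train(frozen, X, epochs=10)
        np.testing.assert_array_equal(trained.weights, frozen.weights)

    def test_zero_epochs_returns_grid(self, rng):
        X = rng.normal(size=(10, 2))
        grid = som.init_grid(1, 2, 2, X, seed=1)
        assert som.train(grid, X, epochs=0) is grid

    def test_two_blobs_units_land_in_distinct_blobs(self, rng):
        X = two_blobs(rng)
        grid = som.train(som.init_grid(1, 2, 4, X, seed=7), X, epochs=100)
        centers = np.array([[0.0] * 4, [8.0] * 4])
        owner = cdist(grid.weights, centers).argmin(axis=1)
        assert set(owner) == {0, 1}

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(40, 3))
        a = som.train(som.init_grid(2, 2, 3, X, seed=9), X, epochs=20)
        b = som.train(som.init_grid(2, 2, 3, X, seed=9), X, epochs=20)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestAssignAndQuality:
    def test_counts_sum_to_m(self, rng):
        X = rng.normal(size=(37, 3))
        grid = som.train(som.init_grid(2, 3, 3, X, seed=1), X, epochs=10)
        assignment = som.assign_clusters(grid, X)
        assert assignment.counts.sum() == 37

    def test_records_equal_to_weights(self, rng):
        grid = som.init_grid(2, 3, 4, rng.normal(size=(20, 4)), seed=2)
        assignment = som.assign_clusters(grid, grid.weights)
        np.testing.assert_array_equal(assignment.counts, np.ones(6, int))

    def test_planted_six_blobs_recovered(self):
        from somdbn import generate_clustered_classes

        table, truth = generate_clustered_classes(
            600, separation=12.0, missing_rates=None, seed=11
        )
        X = (table.values - table.values.mean(0)) / table.values.std(0)
        grid = som.train(som.init_grid(2, 3, 8, X, seed=11), X, epochs=200)
        assignment = som.assign_clusters(grid, X)
        cont = np.zeros((6, 6), int)
        for t, u in zip(truth.true_cluster_id - 1, assignment.unit_index):
            cont[t, u] += 1
        assert cont.max(axis=1).sum() / 600 >= 0.95

    def test_quantization_error_zero_on_weights(self, rng):
        grid = som.init_grid(2, 3, 3, rng.normal(size=(10, 3)), seed=1)
        q = som.map_quality(grid, grid.weights)
        assert q.quantization_error == pytest.approx(0.0, abs=1e-12)

    def test_single_unit_topographic_zero(self, rng):
        X = rng.normal(size=(20, 2))
        grid = som.init_grid(1, 1, 2, X, seed=1)
        assert som.map_quality(grid, X).topographic_error == 0.0

    def test_quantization_matches_brute_force(self, rng):
        X = rng.normal(size=(60, 4))
        grid = som.train(som.init_grid(2, 3, 4, X, seed=2), X, epochs=20)
        q = som.map_quality(grid, X)
        brute = cdist(X, grid.weights).min(axis=1).mean()
        assert q.quantization_error == pytest.approx(brute, rel=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_training_reduces_quantization_error(self, rng, seed):
        X = two_blobs(np.random.default_rng(seed))
        grid = som.init_grid(2, 3, 4, X, seed=seed)
        before = som.map_quality(grid, X).quantization_error
        after = som.map_quality(som.train(grid, X, epochs=100), X).quantization_error
        assert after <= before


class TestSelectionAndSerialization:
    def test_grid_size_selection_prefers_lower_qe(self, rng):
        X = two_blobs(rng, n=60)
        best, results = som.select_grid_size(
            [(1, 1), (1, 2)], X, seed=3, epochs=50
        )
        assert best == (1, 2)
        assert (
            results[(1, 2)].quantization_error
            < results[(1, 1)].quantization_error
        )

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(20, 3))
        grid = som.train(som.init_grid(2, 2, 3, X, seed=5), X, epochs=5)
        back = som.SOMGrid.from_json(grid.to_json())
        np.testing.assert_array_equal(back.weights, grid.weights)
        assert back.epochs_trained == grid.epochs_trained
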