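import numpy as np
import pytest

from somdbn import dbn


def random_tiny_rbm(seed, I=3, J=2, scale=0.8):
    rng = np.random.default_rng(seed)
    return dbn.RBMParams(
        W=rng.normal(0, scale, (I, J)),
        b=rng.normal(0, scale, I),
        a=rng.normal(0, scale, J),
    )


def conditional_from_joint(stats, v_index):
    """p(h_j = 1 | v) derived from the enumerated joint distribution."""
    row = stats.joint[v_index]
    return (row @ stats.hidden_states) / row.sum()


class TestSigmoid:
    def test_midpoint_and_limits(self):
        assert dbn.sigmoid(0.0) == 0.5
        assert dbn.sigmoid(800.0) == pytest.approx(1.0)
        assert dbn.sigmoid(-800.0) == pytest.approx(0.0)

    def test_symmetry(self):
        assert dbn.sigmoid(2.0) + dbn.sigmoid(-2.0) == pytest.approx(1.0, abs=1e-15)


class TestEnergyAndEnumeration:
    def test_zero_states_zero_energy(self):
        params = random_tiny_rbm(0)
        assert dbn.rbm_energy(params, np.zeros(3), np.zeros(2)) == 0.0

    def test_worked_single_unit_case(self):
        params = dbn.RBMParams(W=np.array([[2.0]]), b=np.array([1.0]), a=np.array([-1.0]))
        assert dbn.rbm_energy(params, np.array([1.0]), np.array([1.0])) == -2.0
        stats = dbn.exact_rbm_stats(params)
        assert stats.Z == pytest.approx(1 + np.e + np.exp(-1) + np.exp(2))

    def test_zero_parameters_partition(self):
        params = dbn.RBMParams(W=np.zeros((3, 4)), b=np.zeros(3), a=np.zeros(4))
        assert dbn.exact_rbm_stats(params).Z == pytest.approx(2 ** 7)

    @pytest.mark.parametrize("seed", range(5))
    def test_joint_normalizes(self, seed):
        stats = dbn.exact_rbm_stats(random_tiny_rbm(seed))
        assert stats.joint.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_binary_state_rejected(self):
        params = random_tiny_rbm(1)
        with pytest.raises(ValueError):
            dbn.rbm_energy(params, np.array([0.5, 0, 1]), np.zeros(2))

    def test_enumeration_guard(self):
        params = dbn.RBMParams(W=np.zeros((12, 12)), b=np.zeros(12), a=np.zeros(12))
        with pytest.raises(ValueError, match="enumeration"):
            dbn.exact_rbm_stats(params)


class TestConditionals:
    def test_zero_weights_half(self):
        params = dbn.RBMParams(W=np.zeros((3, 2)), b=np.zeros(3), a=np.zeros(2))
        np.testing.assert_allclose(dbn.hidden_conditional(params, np.ones(3)), 0.5)
        np.testing.assert_allclose(dbn.visible_conditional(params, np.ones(2)), 0.5)

    def test_bias_saturation(self):
        params = dbn.RBMParams(W=np.zeros((2, 2)), b=np.array([-50.0, 0.0]), a=np.array([50.0, 0.0]))
        assert dbn.hidden_conditional(params, np.zeros(2))[0] == pytest.approx(1.0)
        assert dbn.visible_conditional(params, np.zeros(2))[0] == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_match_enumerated_joint(self, seed):
        """Factorized conditionals equal conditionals of the enumerated joint."""
        params = random_tiny_rbm(seed)
        stats = dbn.exact_rbm_stats(params)
        for vi, v in enumerate(stats.visible_states):
            np.testing.assert_allclose(
                dbn.hidden_conditional(params, v),
                conditional_from_joint(stats, vi),
                atol=1e-10,
            )
        for hi, h in enumerate(stats.hidden_states):
            col = stats.joint[:, hi]
            np.testing.assert_allclose(
                dbn.visible_conditional(params, h),
                (col @ stats.visible_states) / col.sum(),
                atol=1e-10,
            )


class TestCD1:
    def test_zero_learning_rate_no_change(self, rng):
        params = random_tiny_rbm(2)
        batch = (rng.random((10, 3)) < 0.5).astype(float)
        new, _ = dbn.cd1_update(params, batch, lr=0.0, momentum=0.0, rng=rng)
        np.testing.assert_array_equal(new.W, params.W)

    def test_mean_update_close_to_exact_gradient(self):
        """Averaged CD-1 statistics within 15 degrees of the exact gradient."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            params = random_tiny_rbm(seed, scale=0.5)
            data = (rng.random((8, 3)) < 0.5).astype(float)
            gW, gb, ga = dbn.exact_loglik_gradient(params, data)
            tiled = np.tile(data, (5000, 1))
            dW, db, da = dbn.cd1_statistics(params, tiled, np.random.default_rng(seed + 100))
            g = np.concatenate([gW.ravel(), gb, ga])
            e = np.concatenate([dW.ravel(), db, da])
            cos = g @ e / (np.linalg.norm(g) * np.linalg.norm(e))
            assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 15.0

    def test_training_reduces_reconstruction_error(self):
        pattern = np.array([1.0, 0.0, 1.0, 0.0])
        X = np.tile(pattern, (20, 1))
        params = dbn.init_rbm(4, 3, seed=1)
        before = dbn.reconstruction_error(params, X)
        trained, errors = dbn.train_rbm(
            params, X, epochs=500, batch_size=20, rng=np.random.default_rng(2)
        )
        assert errors[-1] < before

    def test_momentum_velocity_chained(self, rng):
        params = random_tiny_rbm(3)
        batch = (rng.random((5, 3)) < 0.5).astype(float)
        _, vel = dbn.cd1_update(params, batch, lr=0.1, momentum=0.5, rng=rng)
        new, vel2 = dbn.cd1_update(params, batch, lr=0.0, momentum=0.5, rng=rng, velocity=vel)
        np.testing.assert_allclose(vel2[0], 0.5 * vel[0])


class TestStack:
    def test_shapes_and_determinism(self, rng):
        X = rng.random((30, 5))
        a = dbn.pretrain_stack((5, 16, 8), X, epochs=3, batch_size=10, seed=4)
        b = dbn.pretrain_stack((5, 16, 8), X, epochs=3, batch_size=10, seed=4)
        assert a[0].W.shape == (5, 16) and a[1].W.shape == (16, 8)
        np.testing.assert_array_equal(a[0].W, b[0].W)
        np.testing.assert_array_equal(a[1].W, b[1].W)

    def test_zero_epochs_random_init(self, rng):
        X = rng.random((10, 4))
        stack = dbn.pretrain_stack((4, 6), X, epochs=0, batch_size=5, seed=1)
        assert (stack[0].b == 0).all() and (stack[0].a == 0).all()

    def test_batch_clamp_warns(self, rng):
        X = rng.random((7, 3))
        with pytest.warns(UserWarning, match="clamping"):
            dbn.pretrain_stack((3, 4), X, epochs=1, batch_size=100, seed=1)

    def test_out_of_range_input_rejected(self, rng):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dbn.pretrain_stack((3, 4), rng.normal(size=(10, 3)), epochs=1, batch_size=5, seed=1)


class TestFineTuneAndPredict:
    def test_separable_classes_high_accuracy(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal(0.25, 0.06, (100, 2)), rng.normal(0.75, 0.06, (100, 2))]
        ).clip(0, 1)
        y = np.repeat([0, 1], 100)
        stack = dbn.pretrain_stack((2, 16, 8), X, epochs=200, batch_size=100, seed=5)
        model = dbn.fine_tune(stack, X, y, epochs=200, batch_size=100, seed=6)
        assert (dbn.predict_labels(model, X) == y).mean() >= 0.98
        losses = np.array(model.loss_history)
        assert np.mean(np.diff(losses) <= 1e-12) >= 0.90

    def test_uniform_labels_learned(self, rng):
        X = rng.random((40, 3))
        stack = dbn.pretrain_stack((3, 8, 4), X, epochs=20, batch_size=20, seed=2)
        model = dbn.fine_tune(stack, X, np.ones(40, int), epochs=100, batch_size=20, seed=3)
        assert (dbn.predict_labels(model, X) == 1).all()

    def test_symmetric_network_scores_half(self):
        layers = (
            (np.zeros((3, 4)), np.zeros(4)),
            (np.zeros((4, 1)), np.zeros(1)),
        )
        model = dbn.DBNModel(layers=layers, n_outputs=1)
        assert dbn.predict_proba(model, np.array([[0.3, 0.9, 0.1]]))[0] == 0.5

    def test_forward_pass_matches_manual_arithmetic(self):
        """Oracle: layer-by-layer matrix arithmetic done by hand."""
        W1 = np.array([[0.5, -1.0], [0.25, 0.75]])
        c1 = np.array([0.1, -0.2])
        W2 = np.array([[2.0], [-1.5]])
        c2 = np.array([0.05])
        model = dbn.DBNModel(layers=((W1, c1), (W2, c2)), n_outputs=1)
        x = np.array([0.6, 0.4])
        h = 1 / (1 + np.exp(-(x @ W1 + c1)))
        expected = 1 / (1 + np.exp(-(h @ W2 + c2)))
        assert dbn.predict_proba(model, x[None, :])[0] == pytest.approx(
            expected[0], rel=1e-12
        )

    def test_probabilities_in_open_interval(self, rng):
        X = rng.random((20, 4))
        stack = dbn.pretrain_stack((4, 6, 3), X, epochs=5, batch_size=10, seed=7)
        model = dbn.fine_tune(stack, X, rng.integers(0, 2, 20), epochs=5, batch_size=10, seed=8)
        proba = dbn.predict_proba(model, X)
        assert ((proba > 0) & (proba < 1)).all()

    def test_feature_count_mismatch(self, rng):
        X = rng.random((10, 3))
        stack = dbn.pretrain_stack((3, 4), X, epochs=1, batch_size=5, seed=1)
        model = dbn.fine_tune(stack, X, np.zeros(10, int), epochs=1, batch_size=5, seed=1)
        with pytest.raises(ValueError, match="features"):
            dbn.predict_proba(model, rng.random((5, 4)))

    def test_serialization_round_trip(self, rng):
        X = rng.random((15, 3))
        stack = dbn.pretrain_stack((3, 5), X, epochs=2, batch_size=5, seed=9)
        model = dbn.fine_tune(stack, X, rng.integers(0, 2, 15), epochs=2, batch_size=5, seed=9)
        back = dbn.DBNModel.from_jsonable(model.to_jsonable())
        np.testing.assert_allclose(
            dbn.predict_proba(back, X), dbn.predict_proba(model, X)
        )

    def test_loss_curve_export(self, rng, tmp_path):
        X = rng.random((10, 2))
        stack = dbn.pretrain_stack((2, 3), X, epochs=1, batch_size=5, seed=1)
        model = dbn.fine_tune(stack, X, np.zeros(10, int), epochs=3, batch_size=5, seed=1)
        model.loss_to_csv(tmp_path / "loss.csv")
        import pandas as pd

        assert len(pd.read_csv(tmp_path / "loss.csv")) == 3
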