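import numpy as np
import pytest

import hdxamend as hx
from hdxamend.mlp_corrector import (
    InsufficientDataError,
    NetworkSpec,
    TrainedModel,
    TrainingSet,
    forward,
    init_params,
    loss_and_grads,
    mse,
    predict_controls,
    relu,
    train,
    variance_feature,
)


def functional_training_set(n=500, seed=0, protein="train"):
    """Targets are a fixed smooth function of the variance feature."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.0, 0.15, n)
    targets = np.column_stack([0.55 + 1.5 * v, 0.02 + 0.3 * v])
    return TrainingSet(v, targets, np.array([protein] * n))


class TestElementaryOps:
    def test_variance_examples(self):
        assert variance_feature([0.2, 0.2, 0.2]) == pytest.approx(0.0, abs=1e-30)
        assert variance_feature([0.0, 1.0]) == pytest.approx(0.25)

    def test_variance_permutation_invariant(self):
        x = [0.1, 0.5, 0.3, 0.9]
        assert variance_feature(x) == pytest.approx(variance_feature(x[::-1]))

    def test_variance_needs_two_points(self):
        with pytest.raises(InsufficientDataError):
            variance_feature([0.4])

    def test_relu(self):
        assert relu(-3.2) == 0.0
        assert relu(2.0) == 2.0
        assert relu(0.0) == 0.0

    def test_mse_examples(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mse([0.0, 1.0], [0.0, 0.0]) == pytest.approx(0.5)
        assert mse([0.0, 0.0], [1.0, 1.0]) == pytest.approx(1.0)
        a, b = np.array([0.1, 0.9]), np.array([0.3, 0.2])
        assert mse(a, b) == mse(b, a)

    def test_mse_shape_mismatch(self):
        with pytest.raises(hx.StructuralError):
            mse([1.0], [1.0, 2.0])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients vs central differences on random small nets."""
        rng = np.random.default_rng(1)
        for trial in range(5):
            widths = tuple(int(w) for w in rng.integers(2, 6, size=3))
            spec = NetworkSpec(hidden_layer_widths=widths, seed=trial)
            params = init_params(spec)
            X = rng.normal(size=(7, 1))
            Y = rng.uniform(0, 1, size=(7, 2))
            _, grads = loss_and_grads(params, X, Y)
            h = 1e-6
            for layer in range(len(params)):
                W, b = params[layer]
                for idx in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]:
                    Wp = [(w.copy(), bb.copy()) for w, bb in params]
                    Wm = [(w.copy(), bb.copy()) for w, bb in params]
                    Wp[layer][0][idx] += h
                    Wm[layer][0][idx] -= h
                    num = (loss_and_grads(Wp, X, Y)[0] - loss_and_grads(Wm, X, Y)[0]) / (2 * h)
                    ana = grads[layer][0][idx]
                    assert ana == pytest.approx(num, rel=1e-5, abs=1e-9)


class TestTraining:
    def test_converges_on_functional_set(self):
        model = train(functional_training_set(), None, NetworkSpec(seed=0))
        assert model.train_loss[-1] < 0.1 * model.train_loss[0]
        assert len(model.train_loss) == 1000

    def test_zero_epochs_is_seeded_init(self):
        ts = functional_training_set(50)
        model = train(ts, None, NetworkSpec(epochs=0, seed=3))
        ref = init_params(NetworkSpec(epochs=0, seed=3))
        for (W, b), (W0, b0) in zip(model.params, ref):
            assert np.array_equal(W, W0) and np.array_equal(b, b0)
        assert np.all(np.isfinite(model.predict(ts.features)))

    def test_same_seed_same_weights(self):
        a = train(functional_training_set(100), None, NetworkSpec(epochs=50, seed=4))
        b = train(functional_training_set(100), None, NetworkSpec(epochs=50, seed=4))
        for (Wa, ba), (Wb, bb) in zip(a.params, b.params):
            assert np.array_equal(Wa, Wb) and np.array_equal(ba, bb)

    def test_shared_protein_in_validation_rejected(self):
        ts = functional_training_set(50, protein="p1")
        with pytest.raises(hx.StructuralError):
            train(ts, functional_training_set(10, protein="p1"), NetworkSpec(epochs=1))

    def test_divergence_reports_epoch(self):
        with pytest.raises(hx.HdxError, match="epoch"):
            train(functional_training_set(50), None,
                  NetworkSpec(epochs=200, learning_rate=50.0, seed=0))

    def test_loss_nonincreasing_on_linear_problem(self):
        """Plain GD on an (effectively linear) network and quadratic loss is
        monotone for a small enough learning rate."""
        rng = np.random.default_rng(5)
        v = rng.uniform(-1, 1, 200)
        targets = np.column_stack([0.3 * v + 0.5, -0.1 * v + 0.2])
        ts = TrainingSet((v - v.min()) / np.ptp(v), np.clip(targets, 0, 1),
                         np.array(["p"] * 200))
        model = train(ts, None, NetworkSpec(hidden_layer_widths=(8,),
                                            epochs=300, learning_rate=0.005, seed=6))
        diffs = np.diff(model.train_loss)
        assert np.all(diffs <= 1e-12)

    def test_held_out_prediction_error_small(self):
        model = train(functional_training_set(500, seed=0), None, NetworkSpec(seed=0))
        held = functional_training_set(200, seed=99, protein="held")
        pred = model.predict(held.features)
        mae = np.mean(np.abs(pred - held.targets))
        assert mae < 0.05


class TestApplication:
    def test_identical_time_courses_identical_predictions(self, small_protein):
        model = train(functional_training_set(200), None, NetworkSpec(epochs=100, seed=1))
        table = small_protein["table"].copy()
        table.rfu[1] = table.rfu[0]
        controls = predict_controls(model, table)
        assert controls.rfu_back[0] == controls.rfu_back[1]
        assert controls.rfu_fwd[0] == controls.rfu_fwd[1]
        assert controls.provenance == "predicted_ai"

    def test_predictions_clamped_and_ordered(self, small_protein):
        # adversarial weights: huge negative output bias
        spec = NetworkSpec(hidden_layer_widths=(4,), epochs=0, seed=2)
        model = train(functional_training_set(10), None, spec)
        W, b = model.params[-1]
        model.params[-1] = (W * 0, b - 5.0)
        controls = predict_controls(model, small_protein["table"])
        assert np.all(controls.rfu_back >= 0) and np.all(controls.rfu_back <= 1)
        assert np.all(controls.rfu_back > controls.rfu_fwd)

    def test_oracle_controls_restore_exactly(self, small_protein, sampled_controls):
        err = hx.apply_controls(small_protein["table"], sampled_controls, mode="corrupt")
        restored = hx.apply_controls(err, sampled_controls, mode="correct")
        assert np.allclose(restored.rfu, small_protein["table"].rfu, atol=1e-12)

    def test_correct_with_model_preserves_shape(self, small_protein):
        model = train(functional_training_set(200), None, NetworkSpec(epochs=100, seed=1))
        out = hx.correct_with_model(small_protein["table"], model)
        assert out.rfu.shape == small_protein["table"].rfu.shape
        assert out.map.peptides == small_protein["table"].map.peptides

    def test_json_round_trip(self, tmp_path):
        model = train(functional_training_set(50), None, NetworkSpec(epochs=20, seed=7))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = TrainedModel.from_json(path)
        x = np.array([0.01, 0.05, 0.1])
        assert np.allclose(back.predict(x), model.predict(x), atol=1e-12)
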