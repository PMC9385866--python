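import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finnet.posterior import (
    ConstantPosteriorModel,
    LinearSoftmaxModel,
    MLPConfig,
    MLPPosterior,
    train_mlp,
)

from _utils import logistic_1d_model


def finite_difference_grad_log(model, x, step=1e-5):
    d = x.shape[0]
    out = np.zeros((model.n_classes, d))
    for j in range(d):
        e = np.zeros(d)
        e[j] = step
        lp_plus = np.log(model.predict_posteriors((x + e)[None, :])[0])
        lp_minus = np.log(model.predict_posteriors((x - e)[None, :])[0])
        out[:, j] = (lp_plus - lp_minus) / (2 * step)
    return out


class TestMLPConfig:
    def test_defaults_match_reference_configuration(self):
        config = MLPConfig()
        assert config.hidden_units == 30
        assert config.learning_rate == 0.01
        assert config.momentum == 0.9
        assert config.weight_decay == 0.2

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hidden_units=0),
            dict(learning_rate=0.0),
            dict(momentum=1.0),
            dict(momentum=-0.1),
            dict(weight_decay=-1.0),
            dict(batch_size=0),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MLPConfig(**kwargs)


class TestTrainMLP:
    def test_accuracy_on_separated_blobs(self, blob_data, trained_mlp):
        # nearest-centroid oracle reaches >= 0.99 on this data, so a
        # trained MLP must manage >= 0.95
        spec, features, labels = blob_data
        means = spec.means()
        d2 = ((features[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        assert np.mean(d2.argmin(axis=1) == labels) >= 0.99

        model, _, _ = trained_mlp
        accuracy = np.mean(model.predict_labels(features) == labels)
        assert accuracy >= 0.95

    def test_posteriors_row_stochastic(self, trained_mlp, rng):
        model, features, _ = trained_mlp
        p = model.predict_posteriors(rng.standard_normal((30, features.shape[1])) * 5)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_zero_epoch_training_valid_probabilities(self, blob_data):
        _, features, labels = blob_data
        model = train_mlp(features, labels, MLPConfig(max_epochs=0, seed=1))
        p = model.predict_posteriors(features[:10])
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_reproducible_given_seed(self, blob_data):
        _, features, labels = blob_data
        config = MLPConfig(max_epochs=5, seed=7)
        m1 = train_mlp(features, labels, config)
        m2 = train_mlp(features, labels, config)
        assert np.array_equal(m1.w1, m2.w1)
        assert np.array_equal(m1.w2, m2.w2)

    def test_loss_trend_non_increasing_up_to_noise(self, blob_data):
        _, features, labels = blob_data
        model = train_mlp(features, labels, MLPConfig(max_epochs=60, weight_decay=0.0, seed=0))
        losses = np.asarray(model.loss_history)
        # compare means of the first and last thirds (mini-batch noise)
        assert losses[-20:].mean() < losses[:20].mean()

    def test_weight_decay_shrinks_weights(self, blob_data):
        _, features, labels = blob_data
        base = dict(max_epochs=30, seed=3)
        free = train_mlp(features, labels, MLPConfig(weight_decay=0.0, **base))
        decayed = train_mlp(features, labels, MLPConfig(weight_decay=0.1, **base))
        norm = lambda m: np.sqrt(np.sum(m.w1**2) + np.sum(m.w2**2))
        assert norm(decayed) < norm(free)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            train_mlp(np.random.default_rng(0).standard_normal((10, 3)), np.zeros(10))

    def test_nan_features_rejected(self):
        x = np.ones((10, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_mlp(x, np.arange(10) % 2)


class TestPredictPosteriors:
    def test_duplicate_rows_identical_posteriors(self, trained_mlp):
        model, features, _ = trained_mlp
        x = np.vstack([features[0], features[0]])
        p = model.predict_posteriors(x)
        assert np.array_equal(p[0], p[1])

    def test_zero_weight_linear_softmax_uniform(self):
        model = LinearSoftmaxModel(weights=np.zeros((4, 3)))
        p = model.predict_posteriors(np.random.default_rng(0).standard_normal((5, 4)))
        assert np.allclose(p, 1.0 / 3.0)

    def test_logistic_symmetry_at_origin(self):
        model = logistic_1d_model()
        p = model.predict_posteriors(np.array([[0.0]]))
        assert np.allclose(p, [[0.5, 0.5]])

    def test_dimension_mismatch_rejected(self, trained_mlp):
        model, _, _ = trained_mlp
        with pytest.raises(ValueError, match="features"):
            model.predict_posteriors(np.zeros((2, model.n_inputs + 1)))


class TestGradLogPosteriors:
    def test_constant_model_zero_gradients(self):
        model = ConstantPosteriorModel(np.array([0.3, 0.7]), n_inputs=4)
        assert np.array_equal(model.grad_log_posteriors(np.ones(4)), np.zeros((2, 4)))

    def test_two_class_linear_softmax_closed_form(self, rng):
        # oracle: grad_x log p(1|x) = (1 - p1)(w1 - w0)
        w = rng.standard_normal((3, 2))
        model = LinearSoftmaxModel(weights=w)
        for _ in range(10):
            x = rng.standard_normal(3)
            p1 = model.predict_posteriors(x[None, :])[0, 1]
            g = model.grad_log_posteriors(x)
            expected = (1 - p1) * (w[:, 1] - w[:, 0])
            assert np.allclose(g[1], expected, atol=1e-12)
            fd = finite_difference_grad_log(model, x)
            assert np.allclose(g, fd, rtol=1e-4, atol=1e-6)

    def test_mlp_gradients_match_finite_differences(self, trained_mlp, rng):
        model, features, _ = trained_mlp
        idx = rng.choice(features.shape[0], size=20, replace=False)
        for x in features[idx]:
            g = model.grad_log_posteriors(x)
            fd = finite_difference_grad_log(model, x)
            denom = np.maximum(np.abs(fd), 1e-3)
            assert np.max(np.abs(g - fd) / denom) <= 1e-4

    def test_batch_gradients_match_single(self, trained_mlp):
        model, features, _ = trained_mlp
        batch = model.grad_log_posteriors_batch(features[:5])
        for i in range(5):
            assert np.allclose(batch[i], model.grad_log_posteriors(features[i]), atol=1e-12)

    def test_directional_gradients_consistent(self, trained_mlp, rng):
        model, features, _ = trained_mlp
        x = features[:6]
        deltas = rng.standard_normal(x.shape)
        fast = model.directional_grad_log(x, deltas)
        slow = np.einsum("ncd,nd->nc", model.grad_log_posteriors_batch(x), deltas)
        assert np.allclose(fast, slow, atol=1e-10)


class TestPersistence:
    def test_save_load_roundtrip_bitwise(self, trained_mlp, tmp_path):
        model, features, _ = trained_mlp
        model.save(tmp_path / "mlp.json")
        back = MLPPosterior.load(tmp_path / "mlp.json")
        assert np.array_equal(back.predict_posteriors(features[:8]), model.predict_posteriors(features[:8]))
        assert back.config == model.config


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(-5, 5), min_size=2, max_size=2))
def test_linear_softmax_posteriors_always_normalised(point):
    model = LinearSoftmaxModel(weights=np.array([[1.0, -1.0, 0.5], [0.0, 2.0, -0.5]]))
    p = model.predict_posteriors(np.array([point]))
    assert np.all(p >= 0)
    assert abs(p.sum() - 1.0) < 1e-10
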