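"""Network architecture conformance, training behaviour, and prediction."""

import numpy as np
import pytest

from scalobeat.model import (
    HeartbeatCNN,
    TrainConfig,
    count_parameters,
    cross_entropy,
    learning_rate_at,
    load_model,
    predict,
    save_model,
    train,
)

# Expected layer table: (name, output shape H x W x C, trainable parameters).
EXPECTED_LAYERS = [
    ("input_scalogram", (100, 100, 1), 0),
    ("conv1", (94, 94, 16), 784),
    ("bn1", (94, 94, 16), 64),
    ("relu1", (94, 94, 16), 0),
    ("pool1", (18, 18, 16), 0),
    ("conv2", (16, 16, 32), 4608),
    ("bn2", (16, 16, 32), 128),
    ("relu2", (16, 16, 32), 0),
    ("pool2", (5, 5, 32), 0),
    ("conv3", (3, 3, 64), 18432),
    ("bn3", (3, 3, 64), 256),
    ("relu3", (3, 3, 64), 0),
    ("global_pool", (1, 1, 64), 0),
    ("flatten", (64,), 0),
    ("input_rr", (4,), 0),
    ("concat", (68,), 0),
    ("dense1", (32,), 2208),
    ("dense2", (4,), 132),
]
TOTAL_PARAMETERS = 26_612


@pytest.fixture(scope="module")
def model():
    return HeartbeatCNN(seed=0)


def test_layer_shapes_and_parameter_counts_match_design_table(model):
    rows = model.layer_summary()
    assert [(r.name, r.output_shape, r.n_parameters) for r in rows] == EXPECTED_LAYERS


def test_total_trainable_parameters(model):
    assert model.total_parameters() == TOTAL_PARAMETERS


@pytest.mark.parametrize(
    ("layer", "expected"),
    [("conv1", 784), ("conv3", 18432), ("dense1", 2208), ("bn2", 128)],
)
def test_count_parameters_by_layer(model, layer, expected):
    assert count_parameters(model, layer) == expected


def test_count_parameters_unknown_layer_raises(model):
    with pytest.raises(KeyError):
        count_parameters(model, "conv9")


def test_pooling_uses_floor_division(model):
    rows = {r.name: r.output_shape for r in model.layer_summary()}
    assert rows["pool1"] == (18, 18, 16)  # floor((94-5)/5)+1
    assert rows["pool2"] == (5, 5, 32)  # floor((16-3)/3)+1


@pytest.mark.parametrize(
    ("epoch", "lr"), [(0, 1e-3), (4, 1e-3), (5, 1e-4), (9, 1e-4), (12, 1e-5)]
)
def test_learning_rate_schedule(epoch, lr):
    assert learning_rate_at(epoch, TrainConfig()) == pytest.approx(lr)


def test_degenerate_zero_input_gives_finite_scores(model):
    logits = model.forward(np.zeros((2, 1, 100, 100)), np.zeros((2, 4)))
    assert np.all(np.isfinite(logits))


def test_prediction_tie_breaks_toward_lower_class_index():
    m = HeartbeatCNN(seed=0)
    # force a two-way tie between classes N and SVEB for every input
    m.dense2.W.v[:] = 0.0
    m.dense2.b.v[:] = np.array([0.5, 0.5, 0.0, 0.0], dtype=m.dtype)
    rng = np.random.default_rng(0)
    pred = predict(m, rng.standard_normal((3, 1, 100, 100)), rng.standard_normal((3, 4)))
    assert np.all(pred == 0)  # N wins the tie


def test_batch_prediction_equals_per_item_prediction(rng):
    m = HeartbeatCNN(seed=3)
    x = rng.standard_normal((5, 1, 100, 100))
    rr = rng.standard_normal((5, 4))
    batch = predict(m, x, rr)
    single = np.array([predict(m, x[i : i + 1], rr[i : i + 1])[0] for i in range(5)])
    np.testing.assert_array_equal(batch, single)


def test_eval_mode_is_independent_of_batch_composition(rng):
    m = HeartbeatCNN(seed=4)
    x = rng.standard_normal((6, 1, 100, 100))
    rr = rng.standard_normal((6, 4))
    full = m.forward(x, rr, training=False)
    alone = m.forward(x[:1], rr[:1], training=False)
    np.testing.assert_allclose(full[0], alone[0], rtol=1e-5, atol=1e-6)


def test_prediction_input_validation(model):
    with pytest.raises(ValueError):
        predict(model, np.zeros((2, 100, 100)), np.zeros((2, 4)))
    with pytest.raises(ValueError):
        predict(model, np.zeros((2, 1, 100, 100)), np.zeros((3, 4)))


def test_train_rejects_empty_or_invalid_labels():
    m = HeartbeatCNN(seed=0)
    with pytest.raises(ValueError, match="empty"):
        train(m, np.zeros((0, 1, 100, 100)), np.zeros((0, 4)), np.zeros(0, dtype=int))
    with pytest.raises(ValueError, match="labels"):
        train(
            m,
            np.zeros((2, 1, 100, 100)),
            np.zeros((2, 4)),
            np.array([0, 7]),
            TrainConfig(max_epochs=1, batch_size=2),
        )


def test_backprop_matches_finite_differences():
    """Check analytic gradients of the smooth parameters (conv/dense weights,
    batch-norm scales) against central differences on a float64 model; shift
    parameters are excluded because ReLU sign flips make the numerical
    derivative unreliable at machine-epsilon perturbations."""
    rng = np.random.default_rng(11)
    m = HeartbeatCNN(seed=1, dtype=np.float64)
    x = rng.standard_normal((3, 1, 100, 100)) * 0.5
    rr = rng.standard_normal((3, 4)) * 0.1
    y = np.array([0, 1, 2])

    def loss_fn():
        return cross_entropy(m.forward(x, rr, training=True), y)[0]

    loss, dlogits = cross_entropy(m.forward(x, rr, training=True), y)
    m.zero_grad()
    m.backward(dlogits)
    smooth = [
        m.conv1.W, m.conv2.W, m.conv3.W,
        m.bn1.gamma, m.bn2.gamma, m.bn3.gamma,
        m.dense1.W, m.dense2.W, m.dense2.b,
    ]
    for p in smooth:
        flat, grad = p.v.ravel(), p.g.ravel()
        for i in rng.choice(flat.size, size=2, replace=False):
            eps, old = 1e-6, flat[i]
            flat[i] = old + eps
            up = loss_fn()
            flat[i] = old - eps
            down = loss_fn()
            flat[i] = old
            numeric = (up - down) / (2 * eps)
            assert abs(numeric - grad[i]) <= 1e-5 * max(1.0, abs(numeric))


def test_training_is_deterministic_for_fixed_seed(rng):
    x = rng.standard_normal((8, 1, 100, 100))
    rr = rng.standard_normal((8, 4))
    y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
    cfg = TrainConfig(batch_size=4, max_epochs=2, seed=5)
    states = []
    for _ in range(2):
        m = HeartbeatCNN(seed=5)
        train(m, x, rr, y, cfg)
        states.append(m.state_dict())
    for key in states[0]:
        np.testing.assert_array_equal(states[0][key], states[1][key])


def test_separable_two_class_task_is_learned_quickly(rng):
    """Class-dependent constant blocks are linearly separable; training
    accuracy reaches 99% within ten epochs."""
    n = 200
    x = np.zeros((n, 1, 100, 100))
    y = np.tile([0, 1], n // 2)
    x[y == 0, :, :50, :] = 1.0
    x[y == 1, :, 50:, :] = 1.0
    x += 0.05 * rng.standard_normal(x.shape)
    rr = np.zeros((n, 4))
    m = HeartbeatCNN(seed=2)
    log = train(m, x, rr, y, TrainConfig(batch_size=32, max_epochs=10, seed=2))
    assert len(log) == 10
    accuracy = (predict(m, x, rr) == y).mean()
    assert accuracy >= 0.99
    # loss trend: late epochs better than the start
    assert log[-1]["loss"] < log[0]["loss"]


def test_save_load_round_trip(tmp_path, rng):
    m = HeartbeatCNN(seed=6)
    x = rng.standard_normal((3, 1, 100, 100))
    rr = rng.standard_normal((3, 4))
    path = tmp_path / "model.npz"
    save_model(m, path)
    m2 = load_model(path)
    np.testing.assert_array_equal(
        m.forward(x, rr, training=False), m2.forward(x, rr, training=False)
    )
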