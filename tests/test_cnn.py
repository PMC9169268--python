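"""CNN tests: architecture audit, weighting, training mechanics, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from podxray import cnn as C


def micro_spec(seed=0, **kw):
    """A tiny but structurally complete spec for fast training tests."""
    base = dict(
        input_size=39,
        conv_layers=((8, 5, 1), (16, 3, 1), (16, 3, 1), (16, 3, 1), (8, 3, 1)),
        pool_after=(0, 1),
        fc_layers=(16, 16),
        rng_seed=seed,
    )
    base.update(kw)
    return C.CNNSpec(**base)


# ------------------------------------------------------------------ architecture


def test_default_architecture_inventory():
    """The realized layer list matches the reference recipe exactly."""
    net = C.build_network(C.default_spec())
    desc = net.describe()
    convs = [d for d in desc if d["type"] == "conv"]
    assert [(d["filters"], d["kernel"], d["stride"]) for d in convs] == [
        (96, 11, 4),
        (256, 5, 1),
        (384, 3, 1),
        (384, 3, 1),
        (256, 3, 1),
    ]
    assert all(d["activation"] == "relu" for d in convs)
    pools = [d for d in desc if d["type"] == "maxpool"]
    assert pools == [{"type": "maxpool", "size": 3, "stride": 2}] * 2
    # pools sit directly after conv1 and conv2
    types = [d["type"] for d in desc]
    assert types[:4] == ["conv", "maxpool", "conv", "maxpool"]
    dense = [d for d in desc if d["type"] == "dense"]
    assert [(d["units"], d["activation"]) for d in dense] == [
        (200, "relu"),
        (200, "relu"),
        (2, "linear"),
    ]
    drops = [d for d in desc if d["type"] == "dropout"]
    assert drops == [{"type": "dropout", "rate": 0.5}] * 2
    # dropout follows each hidden dense layer
    assert types[-5:] == ["dense", "dropout", "dense", "dropout", "dense"]


def test_default_spatial_size_table():
    """Valid-padding arithmetic floor((n-k)/s)+1 per stage, input 227."""
    net = C.build_network(C.default_spec())
    assert net.spatial_sizes() == [55, 27, 23, 11, 9, 7, 5]


def test_underflow_raises_naming_layer():
    with pytest.raises(ValueError, match="underflow"):
        C.build_network(C.default_spec(input_size=11))
    with pytest.raises(ValueError, match="underflow"):
        C.build_network(C.default_spec(input_size=100))


def test_default_forward_shape_contract():
    net = C.build_network(C.default_spec())
    x = np.random.default_rng(0).random((1, 1, 227, 227), dtype=np.float32)
    out = net.forward(x)
    assert out.shape == (1, 2)
    assert np.all(np.isfinite(out))


def test_glorot_init_bounds_and_zero_biases():
    net = C.build_network(C.default_spec())
    conv1 = net.layers[0]
    limit = np.sqrt(6.0 / (1 * 121 + 96 * 121))
    assert np.abs(conv1.W).max() <= limit
    assert np.all(conv1.b == 0)


# ------------------------------------------------------------------ sample weights


def test_uniform_histogram_gives_unit_weights():
    targets = np.stack([np.arange(20.0), np.arange(20.0)], axis=1)
    sw = C.compute_sample_weights(targets, n_bins=20)  # one sample per bin
    assert np.allclose(sw.weights, 1.0)


def test_rare_bin_ratio():
    """90/10 split across two bins: raw weight ratio is exactly 9."""
    kernel = np.concatenate([np.zeros(90), np.ones(10)])
    targets = np.stack([kernel, kernel], axis=1)
    sw = C.compute_sample_weights(targets, n_bins=2)
    assert sw.per_trait[-1, 0] / sw.per_trait[0, 0] == pytest.approx(9.0)
    assert sw.weights.mean() == pytest.approx(1.0)


def test_identical_targets_give_uniform_weights():
    targets = np.full((30, 2), 0.5)
    sw = C.compute_sample_weights(targets, n_bins=5)
    assert np.allclose(sw.weights, 1.0)


def test_weights_non_increasing_in_own_bin_count():
    """Duplicating a common sample never increases its own raw weight."""
    rng = np.random.default_rng(0)
    base = rng.uniform(0, 1, size=(30,))
    for _ in range(5):
        t1 = np.stack([base, base], axis=1)
        t2 = np.stack([np.append(base, base[0]), np.append(base, base[0])], axis=1)
        w1 = C.compute_sample_weights(t1, n_bins=5).per_trait[0, 0]
        w2 = C.compute_sample_weights(t2, n_bins=5).per_trait[0, 0]
        assert w2 <= w1 + 1e-12
        base = rng.uniform(0, 1, size=(30,))


def test_sample_weight_validation():
    with pytest.raises(ValueError):
        C.compute_sample_weights(np.zeros((3, 2)), n_bins=5)


# ------------------------------------------------------------------ loss & updates


def test_weighted_mse_with_unit_weights_is_plain_mse():
    rng = np.random.default_rng(1)
    pred, target = rng.random((8, 2)), rng.random((8, 2))
    w = np.ones(8)
    assert C.weighted_mse(pred, target, w) == pytest.approx(
        float(np.mean((pred - target) ** 2)), rel=1e-15
    )


def test_doubling_weights_doubles_loss_keeps_first_step_direction():
    rng = np.random.default_rng(2)
    x = rng.random((6, 1, 39, 39), dtype=np.float32)
    y = rng.random((6, 2)).astype(np.float32)
    w = rng.uniform(0.5, 2.0, size=6).astype(np.float32)

    def one_step(weights):
        net = C.build_network(micro_spec(seed=5, dropout_rate=0.0))
        before = [arr.copy() for _, _, arr, _ in net.parameters()]
        m = C.train(net, x, y, sample_weights=weights, epochs=1)
        after = [arr for _, _, arr, _ in net.parameters()]
        return m.history["train_loss"][0], [a - b for a, b in zip(after, before)]

    loss1, upd1 = one_step(w)
    loss2, upd2 = one_step(2 * w)
    assert loss2 == pytest.approx(2 * loss1, rel=1e-5)
    # Adam normalizes per-parameter step scale: the first update is nearly
    # invariant to a uniform weight rescaling (up to the eps regularizer)
    for a, b in zip(upd1, upd2):
        mask = np.abs(a) > 1e-7
        if mask.any():
            assert np.all(np.sign(a[mask]) == np.sign(b[mask]))
            assert np.allclose(a[mask], b[mask], rtol=5e-2)


def test_non_finite_loss_aborts():
    net = C.build_network(micro_spec(seed=0, dropout_rate=0.0))
    x = np.full((2, 1, 39, 39), np.nan, dtype=np.float32)
    y = np.zeros((2, 2), dtype=np.float32)
    with pytest.raises(RuntimeError, match="non-finite"):
        C.train(net, x, y, epochs=1)


# ------------------------------------------------------------------ training behavior


def _toy_dataset(n=32, seed=0, size=39):
    """Images whose mean brightness encodes both targets (separable by design)."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0.1, 1.5, size=(n, 2)).astype(np.float32)
    x = np.zeros((n, 1, size, size), dtype=np.float32)
    for i in range(n):
        x[i, 0] = y[i, 0] * 0.3
        x[i, 0, : size // 2] += y[i, 1] * 0.3
        x[i, 0] += rng.normal(0, 0.01, size=(size, size))
    return x, y


def test_seeded_training_is_reproducible():
    x, y = _toy_dataset()
    losses = []
    for _ in range(2):
        net = C.build_network(micro_spec(seed=7))
        m = C.train(net, x, y, epochs=1)
        losses.append(m.history["train_loss"][0])
    assert losses[0] == losses[1]


def test_validation_mae_decreases_across_seeds():
    """Learning sanity: val MAE drops from epoch 1 to epoch 30 in >=9/10 seeds."""
    wins = 0
    for seed in range(10):
        x, y = _toy_dataset(n=32, seed=100 + seed)
        xv, yv = _toy_dataset(n=8, seed=200 + seed)
        net = C.build_network(micro_spec(seed=seed, batch_size=16))
        m = C.train(net, x, y, val_images=xv, val_targets=yv, epochs=30)
        h = m.history
        if h["val_mae"].iloc[-1] < h["val_mae"].iloc[0]:
            wins += 1
    assert wins >= 9


def test_history_length_matches_epochs():
    x, y = _toy_dataset(n=8)
    net = C.build_network(micro_spec(seed=1))
    m = C.train(net, x, y, epochs=4)
    assert list(m.history["epoch"]) == [1, 2, 3, 4]
    assert isinstance(m.history, pd.DataFrame)


# ------------------------------------------------------------------ inference


def test_inference_deterministic_and_floored():
    net = C.build_network(micro_spec(seed=3))
    img = np.random.default_rng(4).random((39, 39), dtype=np.float32)
    p1 = C.predict_weights_cnn(net, img[None])
    p2 = C.predict_weights_cnn(net, img[None])
    assert np.array_equal(p1, p2)
    z = C.predict_weights_cnn(net, np.zeros((1, 39, 39), dtype=np.float32))
    assert np.all(np.isfinite(z)) and np.all(z >= 0)


def test_images_to_input_pads_and_resizes():
    img = np.ones((20, 40))
    out = C.images_to_input([img], input_size=39)
    assert out.shape == (1, 39, 39)
    assert out.dtype == np.float32
    # aspect preserved: padded rows are (nearly) zero, content rows are bright
    assert out[0, 19].mean() > 0.5
    assert out[0, 1].mean() < 0.2
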