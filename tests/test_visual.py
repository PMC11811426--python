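"""TSNet-DD: stem geometry, attention algebra, identity collapse, training step."""

import numpy as np
import pytest

from mmdepnet.autodiff import Tensor
from mmdepnet.training import TrainConfig, fit_model, joint_loss
from mmdepnet.visual import (SpatialAttention, TemporalAttention, TSAM,
                             TsnetConfig, TsnetModel, TSNetClassifier)


def small_cfg(**kw):
    base = dict(depth="tsnet32", in_channels=3, base_channels=4,
                attention_reduction=4, feature_dim=8, dropout=0.5)
    base.update(kw)
    return TsnetConfig(**base)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_block_layouts_follow_resnet_18_and_34():
    assert TsnetConfig(depth="tsnet32").blocks_per_stage == (2, 2, 2, 2)
    assert TsnetConfig(depth="tsnet64").blocks_per_stage == (3, 4, 6, 3)


def test_attention_module_counts_match_naming():
    # TAM and SAM counted separately: 8 blocks x 2 sub-modules x 2 modules
    assert TsnetConfig(depth="tsnet32").n_attention_modules == 32
    assert TsnetConfig(depth="tsnet64").n_attention_modules == 64
    assert TsnetConfig(depth="tsnet32").n_tsam == 16
    assert TsnetConfig(depth="tsnet64").n_tsam == 32


def test_instantiated_network_contains_counted_tsams():
    model = TsnetModel(small_cfg(), np.random.default_rng(0))
    tsams = [m for m in model.modules() if isinstance(m, TSAM)]
    assert len(tsams) == 16  # tsnet32: 8 blocks x 2 sub-modules


def test_config_validation():
    with pytest.raises(ValueError):
        small_cfg(dropout=0.3).validate()
    with pytest.raises(ValueError):
        small_cfg(sam_kernel=4).validate()
    with pytest.raises(ValueError):
        small_cfg(depth="tsnet50").validate()


# ---------------------------------------------------------------------------
# stem
# ---------------------------------------------------------------------------

def test_stem_halves_space_twice_and_preserves_time():
    model = TsnetModel(small_cfg(), np.random.default_rng(0))
    out = model.stem(Tensor(np.zeros((1, 3, 8, 64, 64), dtype=np.float32)))
    assert out.shape == (1, 4, 8, 16, 16)


def test_stem_zero_input_zero_bias_gives_zero():
    model = TsnetModel(small_cfg(), np.random.default_rng(0))
    model.stem_conv.bias.data[...] = 0.0
    model.stem_norm.beta.data[...] = 0.0
    out = model.stem(Tensor(np.zeros((1, 3, 8, 32, 32), dtype=np.float32)))
    np.testing.assert_array_equal(out.data, 0.0)


def test_stem_rejects_small_spatial_input():
    model = TsnetModel(small_cfg(), np.random.default_rng(0))
    with pytest.raises(ValueError):
        model.stem(Tensor(np.zeros((1, 3, 8, 16, 16), dtype=np.float32)))


# ---------------------------------------------------------------------------
# temporal attention (channel gate)
# ---------------------------------------------------------------------------

def test_tam_zero_parameters_gate_exactly_half():
    tam = TemporalAttention(4, 4, np.random.default_rng(0))
    for p in tam.parameters():
        p.data[...] = 0.0
    x = np.random.default_rng(1).normal(size=(2, 4, 2, 3, 3)).astype(np.float32)
    w, f_t = tam(Tensor(x))
    np.testing.assert_array_equal(w.data, 0.5)
    np.testing.assert_allclose(f_t.data, 0.5 * x, rtol=1e-6)


def test_tam_constant_channels_double_the_mlp_logit():
    # constant input per channel: avg pool == max pool, logits = 2*MLP(means)
    rng = np.random.default_rng(2)
    tam = TemporalAttention(4, 2, rng)
    means = np.array([0.3, -1.2, 0.7, 2.0], dtype=np.float32)
    x = np.broadcast_to(means[None, :, None, None, None], (1, 4, 2, 2, 2)).copy()
    w, _ = tam(Tensor(x))
    h = np.maximum(means @ tam.fc1.weight.data + tam.fc1.bias.data, 0.0)
    z = h @ tam.fc2.weight.data + tam.fc2.bias.data
    np.testing.assert_allclose(w.data[0], _sigmoid(2.0 * z), rtol=1e-5)


def test_tam_hand_computed_toy():
    """4-channel toy tensor with hand-set MLP weights against pencil algebra."""
    tam = TemporalAttention(4, 4, np.random.default_rng(0))  # hidden size 1
    tam.fc1.weight.data = np.array([[1.0], [0.0], [-1.0], [0.5]], dtype=np.float32)
    tam.fc1.bias.data = np.array([0.1], dtype=np.float32)
    tam.fc2.weight.data = np.array([[1.0, -1.0, 2.0, 0.0]], dtype=np.float32)
    tam.fc2.bias.data = np.array([0.0, 0.2, 0.0, -0.3], dtype=np.float32)
    x = np.arange(4 * 2 * 2 * 2, dtype=np.float32).reshape(1, 4, 2, 2, 2) / 10.0
    w, f_t = tam(Tensor(x))

    avg = x.mean(axis=(2, 3, 4))[0]
    mx = x.max(axis=(2, 3, 4))[0]

    def mlp(v):
        h = max(v @ np.array([1.0, 0.0, -1.0, 0.5]) + 0.1, 0.0)
        return h * np.array([1.0, -1.0, 2.0, 0.0]) + np.array([0.0, 0.2, 0.0, -0.3])

    expected_w = _sigmoid(mlp(avg) + mlp(mx))
    np.testing.assert_allclose(w.data[0], expected_w, rtol=1e-5)
    np.testing.assert_allclose(f_t.data, x * expected_w[None, :, None, None, None],
                               rtol=1e-5)


def test_tam_rejects_indivisible_reduction():
    with pytest.raises(ValueError):
        TemporalAttention(6, 4, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# spatial attention (position gate)
# ---------------------------------------------------------------------------

def test_sam_zero_parameters_gate_exactly_half():
    sam = SpatialAttention(7, np.random.default_rng(0))
    for p in sam.parameters():
        p.data[...] = 0.0
    x = np.random.default_rng(3).normal(size=(2, 4, 2, 8, 8)).astype(np.float32)
    w, f_s = sam(Tensor(x))
    np.testing.assert_array_equal(w.data, 0.5)
    np.testing.assert_allclose(f_s.data, 0.5 * x, rtol=1e-6)


def test_sam_preserves_spatial_shape():
    sam = SpatialAttention(7, np.random.default_rng(0))
    x = np.random.default_rng(4).normal(size=(2, 3, 4, 9, 11)).astype(np.float32)
    w, f_s = sam(Tensor(x))
    assert w.shape == (2, 1, 4, 9, 11)
    assert f_s.shape == x.shape


def test_sam_single_pixel_closed_form():
    sam = SpatialAttention(1, np.random.default_rng(0))  # 1x1 kernel
    w_avg, w_max, b = 0.7, -0.4, 0.25
    sam.conv.weight.data = np.array([[[[[w_avg]]], [[[w_max]]]]], dtype=np.float32)
    sam.conv.bias.data = np.array([b], dtype=np.float32)
    x = np.array([1.0, 3.0, -2.0]).reshape(1, 3, 1, 1, 1).astype(np.float32)
    w, _ = sam(Tensor(x))
    expected = _sigmoid(w_avg * x.mean() + w_max * x.max() + b)
    np.testing.assert_allclose(w.data.ravel()[0], expected, rtol=1e-6)


def test_sam_rejects_even_kernel():
    with pytest.raises(ValueError):
        SpatialAttention(6, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# TSAM and network-wide identity
# ---------------------------------------------------------------------------

def test_tsam_zero_parameters_is_identity():
    tsam = TSAM(4, 4, 7, np.random.default_rng(0))
    tsam.zero_parameters()
    x = np.random.default_rng(5).normal(size=(2, 4, 2, 6, 6)).astype(np.float32)
    np.testing.assert_allclose(tsam(Tensor(x)).data, x, rtol=1e-5, atol=1e-6)


def test_tsam_zero_input_gives_zero():
    tsam = TSAM(4, 4, 7, np.random.default_rng(1))
    out = tsam(Tensor(np.zeros((1, 4, 2, 6, 6), dtype=np.float32)))
    np.testing.assert_array_equal(out.data, 0.0)


def test_tsam_equals_sum_of_components():
    tsam = TSAM(4, 2, 5, np.random.default_rng(2))
    x = Tensor(np.random.default_rng(6).normal(size=(2, 4, 4, 6, 6)).astype(np.float32))
    _, f_t = tsam.tam(x)
    _, f_s = tsam.sam(x)
    np.testing.assert_allclose(tsam(x).data, f_t.data + f_s.data, rtol=1e-6)


def test_gates_strictly_inside_unit_interval():
    rng = np.random.default_rng(7)
    tsam = TSAM(4, 4, 7, rng)
    x = Tensor(rng.normal(size=(2, 4, 3, 6, 6)).astype(np.float32))
    w_t, _ = tsam.tam(x)
    w_s, _ = tsam.sam(x)
    for w in (w_t.data, w_s.data):
        assert np.all(w > 0.0) and np.all(w < 1.0)


def test_zeroed_attention_collapses_to_plain_backbone():
    """Zeroing every TAM/SAM parameter leaves the attention-free network."""
    rng_seed = 11
    with_att = TsnetModel(small_cfg(), np.random.default_rng(rng_seed))
    without = TsnetModel(small_cfg(use_tsam=False), np.random.default_rng(rng_seed))
    # share backbone weights, zero the attention
    state = {k: v for k, v in with_att.state_dict().items() if "tsam" not in k}
    without.load_state_dict(state)
    with_att.zero_attention_parameters()
    with_att.eval(), without.eval()
    x = Tensor(np.random.default_rng(8).normal(size=(2, 3, 8, 32, 32)).astype(np.float32))
    f_a, z_a, p_a = with_att(x)
    f_b, z_b, p_b = without(x)
    np.testing.assert_allclose(f_a.data, f_b.data, rtol=1e-4, atol=1e-5)
    np.testing.assert_allclose(z_a.data, z_b.data, rtol=1e-4, atol=1e-5)


# ---------------------------------------------------------------------------
# full forward / estimator
# ---------------------------------------------------------------------------

def test_forward_deterministic_and_permutation_consistent():
    model = TsnetModel(small_cfg(), np.random.default_rng(9))
    model.eval()
    clip = np.random.default_rng(10).random((1, 3, 8, 32, 32)).astype(np.float32)
    batch = Tensor(np.concatenate([clip, clip]))
    feat, logits, phq8 = model(batch)
    np.testing.assert_array_equal(feat.data[0], feat.data[1])
    feat2, _, _ = model(Tensor(np.concatenate([clip, clip])))
    np.testing.assert_array_equal(feat.data, feat2.data)


def test_single_training_step_decreases_loss():
    rng = np.random.default_rng(12)
    model = TsnetModel(small_cfg(), rng)
    x = rng.random((4, 3, 8, 32, 32)).astype(np.float32)
    labels = np.array([0, 1, 0, 1])
    phq8 = np.array([2.0, 20.0, 5.0, 15.0]) / 24.0
    cfg = TrainConfig(lr=1e-2, iterations=1, batch_size=4, seed=0,
                      weight_decay=0.0, log_every=1)

    def sampler(_rng):
        return {"inputs": x, "label": labels, "phq8": phq8}

    def forward(m, inputs):
        return m(Tensor(inputs))

    model.train()
    model.dropout.p = 0.0  # isolate the optimisation effect
    _, z0, p0 = model(Tensor(x))
    loss0 = float(joint_loss(z0, p0, labels, phq8).data)
    fit_model(model, sampler, forward, cfg)
    model.train()
    _, z1, p1 = model(Tensor(x))
    loss1 = float(joint_loss(z1, p1, labels, phq8).data)
    assert loss1 < loss0


def test_estimator_fit_predict_api(rng):
    X = rng.random((6, 6, 32, 32, 3), dtype=np.float64)
    y = np.array([0, 1, 0, 1, 0, 1])
    est = TSNetClassifier(iterations=3, batch_size=4, feature_dim=8,
                          base_channels=4, attention_reduction=4, seed=0)
    est.fit(X, y)
    assert est.predict(X).shape == (6,)
    proba = est.predict_proba(X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, rtol=1e-5)
    assert est.transform(X).shape == (6, 8)
    assert est.predict_severity(X).shape == (6,)
    assert est.get_params()["iterations"] == 3
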