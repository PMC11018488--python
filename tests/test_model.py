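"""Architecture contracts of the counting network.

Covers the backbone tap shapes, pyramid fusion (including a 1-channel
identity-kernel toy whose output is hand-computable), the MP module,
head output shapes, elementwise mask gating, checkpointing, and an
end-to-end finite-difference check of the full backward pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import flowernet as fn
from flowernet.model import (Backbone, FlowerNetConfig, MPModule,
                             PyramidFusion, gate_density, predict_pair)
from flowernet.nn import MaxPool2


def small_net(seed=0, **cfg_kwargs):
    net = fn.FlowerNet(FlowerNetConfig(**cfg_kwargs))
    fn.init_weights_uniform(net, 0.05, seed)
    return net


# ---------------------------------------------------------------------------
# backbone

def test_backbone_tap_shapes_at_256():
    net = small_net()
    x = np.random.default_rng(0).random((1, 3, 256, 256), dtype=np.float32)
    pyr = net.backbone.forward(x)
    assert pyr.C2.shape == (1, 128, 128, 128)
    assert pyr.C3.shape == (1, 256, 64, 64)
    assert pyr.C4.shape == (1, 512, 32, 32)
    assert pyr.C5.shape == (1, 512, 16, 16)


def test_backbone_is_13_conv_layers():
    from flowernet.nn import Conv2d
    bb = Backbone()
    assert sum(isinstance(op, Conv2d) for op in bb.ops) == 13


def test_backbone_zero_weights_give_zero_taps():
    net = fn.FlowerNet()  # all params start at zero
    x = np.random.default_rng(1).random((1, 3, 64, 64), dtype=np.float32)
    pyr = net.backbone.forward(x)
    for tap in (pyr.C2, pyr.C3, pyr.C4, pyr.C5):
        assert not tap.any()


def test_backbone_rejects_undersized_input():
    net = small_net()
    with pytest.raises(ValueError):
        net.backbone.forward(np.zeros((1, 3, 16, 64), dtype=np.float32))


def test_forward_is_deterministic():
    net = small_net(seed=5)
    x = np.random.default_rng(2).random((1, 3, 48, 48), dtype=np.float32)
    m1, d1 = net.forward(x)
    m2, d2 = net.forward(x)
    np.testing.assert_array_equal(m1, m2)
    np.testing.assert_array_equal(d1, d2)


# ---------------------------------------------------------------------------
# fusion

def test_fusion_output_channels_default():
    net = small_net()
    x = np.random.default_rng(0).random((1, 3, 64, 64), dtype=np.float32)
    fused = net.fusion.forward(net.backbone.forward(x))
    assert fused.shape == (1, 256, 32, 32)  # fusion_channels @ stride 2

    net128 = small_net(fusion_channels=128)
    fused = net128.fusion.forward(net128.backbone.forward(x))
    assert fused.shape == (1, 128, 32, 32)


def test_fusion_zero_unification_weights_give_zero_map():
    net = small_net(seed=3)
    for name, p in net.fusion.params():
        if "lateral" in name or name.endswith(".bias"):
            p.value[...] = 0.0
    x = np.random.default_rng(0).random((1, 3, 64, 64), dtype=np.float32)
    fused = net.fusion.forward(net.backbone.forward(x))
    assert not fused.any()


def _identity_conv(conv):
    conv.weight.value[...] = 0.0
    k = conv.k
    conv.weight.value[0, 0, k // 2, k // 2] = 1.0
    conv.bias.value[...] = 0.0


def test_fusion_identity_toy_matches_hand_computed_sum():
    """1-channel pyramid with identity kernels: fused map equals
    C2 + up(C3) + up²(C4) + up³(C5) under nearest-neighbour doubling."""
    cfg = FlowerNetConfig()
    cfg.fusion_channels = 1  # bypass the {128,256} ablation guard on purpose

    class TinyFusion(PyramidFusion):
        # 1-channel taps so identity kernels make the algebra hand-checkable
        TAP_CHANNELS = {"C2": 1, "C3": 1, "C4": 1, "C5": 1}
        TAP_CHANNELS = {"C2": 1, "C3": 1, "C4": 1, "C5": 1}

    tf = TinyFusion(cfg)
    for lv in tf.levels:
        _identity_conv(tf.lateral[lv])
        for conv, _, _ in tf.upstages[lv]:
            _identity_conv(conv)
    _identity_conv(tf.f)
    _identity_conv(tf.f1x1)

    rng = np.random.default_rng(9)
    c2 = rng.random((1, 1, 8, 8)).astype(np.float32)
    c3 = rng.random((1, 1, 4, 4)).astype(np.float32)
    c4 = rng.random((1, 1, 2, 2)).astype(np.float32)
    c5 = rng.random((1, 1, 1, 1)).astype(np.float32)
    fused = tf.forward(fn.FeaturePyramid(c2, c3, c4, c5))

    def up(a):
        return a.repeat(2, axis=2).repeat(2, axis=3)

    expected = c2 + up(c3) + up(up(c4)) + up(up(up(c5)))
    np.testing.assert_allclose(fused, expected, rtol=1e-5)


def test_non_multiscale_uses_only_c2():
    net = small_net(use_multiscale=False)
    assert net.fusion.levels == ["C2"]
    x = np.random.default_rng(0).random((1, 3, 32, 32), dtype=np.float32)
    mask_prob, density = net.forward(x)
    assert density.shape == (1, 1, 4, 4)


# ---------------------------------------------------------------------------
# MP module

def test_mp_module_shape_contract():
    mp = MPModule(256)
    rng = np.random.default_rng(0)
    for _, p in mp.params():
        p.value[...] = rng.normal(0, 0.05, p.value.shape).astype(np.float32)
    x = rng.random((1, 256, 64, 64)).astype(np.float32)
    assert mp.forward(x).shape == (1, 256, 32, 32)


def test_mp_module_zero_weights_zero_output():
    mp = MPModule(4)
    x = np.ones((1, 4, 8, 8), dtype=np.float32)
    assert not mp.forward(x).any()


def test_mp_branch_a_reproduces_plain_max_pooling():
    mp = MPModule(2)
    # identity 1×1 conv selecting channel 0 in branch A
    mp.conv_a.weight.value[...] = 0.0
    mp.conv_a.weight.value[0, 0, 0, 0] = 1.0
    x = np.random.default_rng(4).random((1, 2, 4, 4)).astype(np.float32)
    y = mp.forward(x)
    ref = MaxPool2().forward(x[:, :1])
    np.testing.assert_allclose(y[:, :1], ref, rtol=1e-6)


def test_mp_module_rejects_odd_channels():
    with pytest.raises(ValueError):
        MPModule(3)


# ---------------------------------------------------------------------------
# head + gating

@pytest.mark.parametrize("hw", [(32, 32), (33, 47), (64, 50)])
@pytest.mark.parametrize("stride", [4, 8, 16])
def test_output_shape_contract(hw, stride):
    net = small_net(output_stride=stride)
    h, w = hw
    x = np.random.default_rng(0).random((1, 3, h, w), dtype=np.float32)
    mask_prob, density = net.forward(x)
    expected = (1, 1, -(-h // stride), -(-w // stride))
    assert mask_prob.shape == expected
    assert density.shape == expected
    assert (density >= 0).all()
    assert ((mask_prob > 0) & (mask_prob < 1)).all()


def test_mask_branch_off_sums_density_directly():
    net = small_net(use_mask_branch=False)
    mask_prob, density = net.forward(
        np.random.default_rng(0).random((1, 3, 32, 32), dtype=np.float32))
    assert mask_prob is None
    img = fn.ImageRecord("t", np.random.default_rng(1).integers(
        0, 256, (32, 32, 3), dtype=np.uint8))
    final, x_mask, count = fn.predict_count(net, img)
    assert (x_mask.values == 1).all()
    assert abs(count - final.values.sum()) < 1e-9


def test_gate_density_forced_arithmetic():
    density = np.array([[0.5, 0.5], [1.0, 0.0]])
    x_mask = np.array([[1, 0], [1, 1]], dtype=np.uint8)
    final = gate_density(density, x_mask)
    np.testing.assert_array_equal(final, [[0.5, 0.0], [1.0, 0.0]])
    assert final.sum() == 1.5
    np.testing.assert_array_equal(gate_density(density, np.ones_like(x_mask)),
                                  density)
    assert not gate_density(density, np.zeros_like(x_mask)).any()


def test_gating_zeroes_background_and_bounds_count(rng):
    for _ in range(25):
        density = rng.random((6, 7))
        x_mask = (rng.random((6, 7)) < 0.5).astype(np.uint8)
        final = gate_density(density, x_mask)
        assert (final[x_mask == 0] == 0).all()
        assert final.sum() <= density.sum() + 1e-12
        assert abs(final.sum() - float((density * x_mask).sum())) < 1e-12


def test_predict_pair_thresholds_mask():
    net = small_net(seed=2)
    x = np.random.default_rng(0).random((1, 3, 32, 32), dtype=np.float32)
    pair = predict_pair(net, x)
    np.testing.assert_array_equal(
        pair.x_mask, (pair.mask_prob >= 0.5).astype(np.uint8))


def test_predict_count_with_panicle_mask(small_scene):
    net = small_net(seed=1)
    _, _, count_full = fn.predict_count(net, small_scene.image)
    final, x_mask, count = fn.predict_count(net, small_scene.image,
                                            small_scene.panicle_mask, pad=2)
    assert np.isfinite(count)
    assert final.values.shape == x_mask.values.shape


# ---------------------------------------------------------------------------
# persistence + config

def test_checkpoint_round_trip(tmp_path):
    net = small_net(seed=8, fusion_channels=128)
    x = np.random.default_rng(0).random((1, 3, 32, 32), dtype=np.float32)
    m1, d1 = net.forward(x)
    path = tmp_path / "ckpt.npz"
    net.save(path)
    back = fn.FlowerNet.load(path)
    assert back.config == net.config
    m2, d2 = back.forward(x)
    np.testing.assert_array_equal(m1, m2)
    np.testing.assert_array_equal(d1, d2)


def test_config_validation():
    with pytest.raises(ValueError):
        FlowerNetConfig(fusion_channels=64)
    with pytest.raises(ValueError):
        FlowerNetConfig(output_stride=6)
    with pytest.raises(ValueError):
        FlowerNetConfig(mask_threshold=1.5)
    with pytest.raises(ValueError):
        FlowerNetConfig(density_branch_downsampling="avg")


# ---------------------------------------------------------------------------
# end-to-end gradient check

def test_full_backward_matches_finite_differences():
    """Finite-difference spot check of d(combined loss)/dθ through the
    whole network — catches any mis-wired gradient path."""
    from flowernet import losses as L
    net = small_net(seed=6)
    # push the head outputs away from the ReLU kink so the finite
    # difference measures the smooth part of the loss surface
    for name, p in net.parameters():
        if name in ("density.out.bias", "mask.out.bias"):
            p.value[...] = 0.5
    rng = np.random.default_rng(0)
    x = rng.random((1, 3, 32, 32), dtype=np.float32)
    gt_m = (rng.random((1, 1, 4, 4)) < 0.5).astype(np.float64)
    gt_d = rng.random((1, 1, 4, 4))

    def loss():
        mp, de = net.forward(x)
        return L.combined_loss(L.mask_loss(mp, gt_m),
                               L.regression_loss(de, gt_d), 8.0)

    params = net.parameters()
    mp, de = net.forward(x)
    for _, p in params:
        p.zero_grad()
    net.backward(L.mask_loss_grad(mp, gt_m),
                 8.0 * L.regression_loss_grad(de, gt_d))

    # directional derivative along the analytic gradient: robust to
    # float32 evaluation noise that swamps single-weight differences
    gnorm = float(np.sqrt(sum(float(np.square(p.grad).sum())
                              for _, p in params)))
    assert gnorm > 0
    h = 3e-3
    for _, p in params:
        p.value += (h / gnorm) * p.grad
    fp = loss()
    for _, p in params:
        p.value -= (2 * h / gnorm) * p.grad
    fm = loss()
    for _, p in params:
        p.value += (h / gnorm) * p.grad
    numeric = (fp - fm) / (2 * h)
    # 10% band: remaining ReLU subgradient ambiguity contributes a few
    # percent; genuine wiring errors show up as factor-level mismatches
    assert abs(numeric - gnorm) < 0.10 * gnorm, \
        f"directional derivative {numeric} vs |grad| {gnorm}"
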