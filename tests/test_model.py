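import numpy as np
import pytest

from vstseg.model import (
    MODES,
    MultiHeadSelfAttention,
    TransformerLayer,
    VSTConfig,
    VSTNet,
    msa,
    self_attention,
    token_count,
)
from vstseg.nn import Tensor

RNG = np.random.default_rng(77)

TINY = dict(stages=3, base_channels=8, depth=2, heads=2, input_size=(64, 64))


def _np_softmax(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# configuration laws
# ---------------------------------------------------------------------------

def test_token_count_law():
    for side in (64, 128, 256):
        assert token_count((side, side), stages=4) == side * side // 256
    assert token_count((64, 32), stages=3) == 64 * 32 // 64
    assert VSTConfig(input_size=(256, 256)).token_count == 256


def test_channel_schedule_doubles():
    cfg = VSTConfig(**TINY)
    assert cfg.channel_schedule == [8, 16, 32]
    assert cfg.bottleneck_channels == 32
    assert cfg.fused_channels == 64  # two encoders
    assert VSTConfig(**{**TINY, "mode": "unet"}).fused_channels == 32


def test_config_validation():
    with pytest.raises(ValueError):
        VSTConfig(mode="resnet")
    with pytest.raises(ValueError):
        VSTConfig(input_size=(100, 100), stages=4)  # not divisible by 16
    with pytest.raises(ValueError):
        VSTConfig(**{**TINY, "heads": 7})  # token dim not divisible
    with pytest.raises(ValueError):
        VSTConfig(n_classes=1)


def test_mode_properties():
    assert [VSTConfig(**{**TINY, "mode": m}).n_encoders for m in MODES] == [1, 2, 2, 2]
    assert [VSTConfig(**{**TINY, "mode": m}).uses_transformer for m in MODES] == [
        False, False, True, True]


# ---------------------------------------------------------------------------
# attention oracles
# ---------------------------------------------------------------------------

def test_self_attention_matches_hand_formula():
    x = RNG.normal(size=(4, 6))
    wq, wk, wv = (RNG.normal(size=(6, 6)) for _ in range(3))
    got = self_attention(x, wq, wk, wv)
    att = _np_softmax((x @ wq) @ (x @ wk).T / np.sqrt(6))
    np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-12)
    np.testing.assert_allclose(got, x + att @ (x @ wv), atol=1e-12)


def test_single_token_attention_is_residual_value():
    x = RNG.normal(size=(1, 5))
    wq, wk, wv = (RNG.normal(size=(5, 5)) for _ in range(3))
    np.testing.assert_allclose(self_attention(x, wq, wk, wv), x + x @ wv,
                               atol=1e-12)


def test_msa_one_head_identity_wo_collapses_to_self_attention():
    x = RNG.normal(size=(3, 4))
    wq, wk, wv = (RNG.normal(size=(4, 4)) for _ in range(3))
    got = msa(x, [(wq, wk, wv)], np.eye(4))
    np.testing.assert_allclose(got, self_attention(x, wq, wk, wv), atol=1e-12)


def test_msa_two_heads_matches_manual_concat():
    x = RNG.normal(size=(3, 4))
    heads = [tuple(RNG.normal(size=(4, 2)) for _ in range(3)) for _ in range(2)]
    wo = RNG.normal(size=(4, 4))
    outs = []
    for wq, wk, wv in heads:
        a = _np_softmax((x @ wq) @ (x @ wk).T / np.sqrt(2))
        outs.append(a @ (x @ wv))
    expected = x + np.concatenate(outs, axis=-1) @ wo
    np.testing.assert_allclose(msa(x, heads, wo), expected, atol=1e-12)


def test_msa_permutation_equivariance():
    """No positional dependence inside MSA: permuting tokens commutes."""
    x = RNG.normal(size=(5, 4))
    heads = [tuple(RNG.normal(size=(4, 2)) for _ in range(3)) for _ in range(2)]
    wo = RNG.normal(size=(4, 4))
    perm = RNG.permutation(5)
    np.testing.assert_allclose(msa(x[perm], heads, wo), msa(x, heads, wo)[perm],
                               atol=1e-10)


def test_msa_module_matches_numpy_oracle():
    mod = MultiHeadSelfAttention(d=8, h=2, rng=np.random.default_rng(1))
    x = RNG.normal(size=(1, 5, 8)).astype(np.float32)
    got = mod(Tensor(x)).data[0]
    heads = [(mod.wq[i].data.astype(np.float64),
              mod.wk[i].data.astype(np.float64),
              mod.wv[i].data.astype(np.float64)) for i in range(2)]
    expected = msa(x[0].astype(np.float64), heads, mod.wo.data.astype(np.float64))
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_transformer_layer_strict_composition():
    """pre_norm=False is exactly y = MSA(x); out = y + MLP(y)."""
    layer = TransformerLayer(d=6, h=2, rng=np.random.default_rng(3), pre_norm=False)
    x = Tensor(RNG.normal(size=(1, 4, 6)).astype(np.float32))
    y = layer.msa(x)
    expected = (y + layer.mlp(y)).data
    np.testing.assert_allclose(layer(x).data, expected, atol=1e-6)


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

def test_encoder_downsampling_and_token_geometry():
    cfg = VSTConfig(**TINY)
    net = VSTNet(cfg, seed=0)
    x = RNG.normal(size=(1, 1, 64, 64)).astype(np.float32)
    skips, bott = net.encoder_image(Tensor(x))
    assert [s.data.shape[-1] for s in skips] == [64, 32, 16]
    assert bott.data.shape == (1, 32, 8, 8)
    assert bott.data.shape[-2] * bott.data.shape[-1] == cfg.token_count


def test_forward_output_shapes_and_aux_heads():
    cfg = VSTConfig(**TINY)
    net = VSTNet(cfg, seed=0)
    img = RNG.random((2, 64, 64)).astype(np.float32)
    sal = RNG.random((2, 64, 64)).astype(np.float32)
    out = net(img, sal)
    assert out["scores"].data.shape == (2, 7, 64, 64)
    assert [a.data.shape[-1] for a in out["aux"]] == [16, 32]  # levels 2, 1
    assert all(a.data.shape[1] == 7 for a in out["aux"])


def test_initial_prediction_is_uniform():
    """Zero-initialised score heads start at the uniform class distribution."""
    net = VSTNet(VSTConfig(**TINY), seed=0)
    img = RNG.random((1, 64, 64)).astype(np.float32)
    sal = RNG.random((1, 64, 64)).astype(np.float32)
    scores = net(img, sal)["scores"].data
    np.testing.assert_allclose(scores, 0.0, atol=0)


def test_mode_input_contract():
    img = RNG.random((1, 64, 64)).astype(np.float32)
    with pytest.raises(ValueError):
        VSTNet(VSTConfig(**TINY), seed=0)(img)  # vst needs saliency
    with pytest.raises(ValueError):
        VSTNet(VSTConfig(**{**TINY, "mode": "unet"}), seed=0)(img, img)


def test_input_size_mismatch_raises():
    net = VSTNet(VSTConfig(**{**TINY, "mode": "unet"}), seed=0)
    with pytest.raises(ValueError):
        net(RNG.random((1, 32, 32)).astype(np.float32))


def test_forward_determinism():
    img = RNG.random((1, 64, 64)).astype(np.float32)
    a = VSTNet(VSTConfig(**{**TINY, "mode": "multi_unet"}), seed=5)(img)
    b = VSTNet(VSTConfig(**{**TINY, "mode": "multi_unet"}), seed=5)(img)
    np.testing.assert_array_equal(a["scores"].data, b["scores"].data)


def test_parameter_count_ladder():
    """Each ablation rung adds capacity; the last two share the exact count."""
    counts = {m: VSTNet(VSTConfig(**{**TINY, "mode": m}), seed=0).n_parameters()
              for m in MODES}
    assert counts["unet"] < counts["multi_unet"] < counts["multi_unet_transformer"]
    assert counts["multi_unet_transformer"] == counts["vst"]
    net = VSTNet(VSTConfig(**TINY), seed=0)
    transformer_params = net.transformer.n_parameters()
    assert counts["multi_unet_transformer"] - counts["multi_unet"] == transformer_params


def test_embed_adds_positions_to_flattened_tokens():
    net = VSTNet(VSTConfig(**TINY), seed=0)
    feat = RNG.normal(size=(1, 64, 8, 8)).astype(np.float32)
    tokens = net.transformer.embed(Tensor(feat)).data
    flat = feat.reshape(1, 64, 64).transpose(0, 2, 1)
    np.testing.assert_allclose(tokens, flat + net.transformer.pos.data, atol=1e-6)
    assert np.abs(net.transformer.pos.data).max() <= 0.04


def test_fuse_concatenates_channels():
    net = VSTNet(VSTConfig(**TINY), seed=0)
    a = Tensor(RNG.normal(size=(1, 3, 4, 4)).astype(np.float32))
    b = Tensor(RNG.normal(size=(1, 5, 4, 4)).astype(np.float32))
    fused = net.fuse(a, b)
    assert fused.data.shape == (1, 8, 4, 4)
    np.testing.assert_array_equal(fused.data[:, :3], a.data)
    assert net.fuse(a, None) is a
    with pytest.raises(ValueError):
        net.fuse(a, Tensor(RNG.normal(size=(1, 5, 2, 2)).astype(np.float32)))


def test_save_load_roundtrip(tmp_path):
    net = VSTNet(VSTConfig(**TINY), seed=9)
    img = RNG.random((1, 64, 64)).astype(np.float32)
    sal = RNG.random((1, 64, 64)).astype(np.float32)
    # perturb so outputs are nonzero despite zero-init heads
    for p in net.parameters():
        p.data += 0.01
    before = net(img, sal)["scores"].data
    net.save(tmp_path / "ckpt.npz")
    loaded = VSTNet.load(tmp_path / "ckpt.npz")
    np.testing.assert_array_equal(loaded(img, sal)["scores"].data, before)
    assert loaded.config == net.config


def test_predict_labels_are_valid_classes():
    net = VSTNet(VSTConfig(**{**TINY, "mode": "unet"}), seed=0)
    for p in net.parameters():
        p.data += 0.01
    pred = net.predict_labels(RNG.random((2, 64, 64)).astype(np.float32))
    assert pred.shape == (2, 64, 64)
    assert pred.min() >= 0 and pred.max() < 7
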