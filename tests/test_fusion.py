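"""Knowledge-sharing transforms, alignment loss, fusion, decoder and pose loss:
worked examples, brute-force oracles, and spec'd invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metagait import nn
from metagait.autodiff import Tensor, no_grad
from metagait.errors import ConfigurationError, DomainError
from metagait.fusion import (Decoder, FusionBranch, FusionNetwork, PoseModel,
                             PoseModelConfig, PretrainConfig, SharedSpaceParams,
                             decode, fuse, knowledge_sharing_loss, pose_loss,
                             pretrain, transform_feature)
from metagait.pipeline import desk_model_config

RNG = np.random.default_rng(11)


# ------------------------------------------------------------------ transforms
def test_identity_initialized_transform_is_identity():
    params = SharedSpaceParams(np.random.default_rng(0), {"image": 5, "emg": 5},
                               shared_dim=5)
    params.transform_image.identity_init()
    x = RNG.standard_normal(5).astype(np.float32)
    out = transform_feature(x, params, "image")
    assert np.allclose(out.data, x.reshape(out.shape), atol=1e-7)


def test_zero_input_through_zero_bias_transform_is_zero():
    params = SharedSpaceParams(np.random.default_rng(0), {"emg": 4}, 6)
    out = transform_feature(np.zeros(4, dtype=np.float32), params, "emg")
    assert np.allclose(out.data, 0.0, atol=1e-7)   # bias initializes to zero


def test_transform_matches_manual_affine_map():
    params = SharedSpaceParams(np.random.default_rng(3), {"vio": 4}, 3)
    x = RNG.standard_normal(4).astype(np.float32)
    lin = params.transform_vio.linear
    expect = lin.weight.data @ x + lin.bias.data
    assert np.allclose(transform_feature(x, params, "vio").data, expect, atol=1e-6)


def test_transform_unknown_modality_rejected():
    params = SharedSpaceParams(np.random.default_rng(0), {"emg": 4}, 4)
    with pytest.raises(DomainError):
        transform_feature(np.zeros(4), params, "image")


# -------------------------------------------------------------- alignment loss
def test_ks_loss_zero_when_features_coincide():
    f = Tensor(RNG.standard_normal((3, 8)))
    loss = knowledge_sharing_loss({"image": f, "emg": f, "vio": f})
    assert loss.item() == pytest.approx(0.0, abs=1e-5)


def test_ks_loss_two_modalities_three_four_five():
    feats = {"image": Tensor(np.zeros(2)), "emg": Tensor(np.array([3.0, 4.0]))}
    assert knowledge_sharing_loss(feats).item() == pytest.approx(5.0, rel=1e-6)


def test_ks_loss_matches_pairwise_brute_force_and_is_order_invariant():
    feats = {m: RNG.standard_normal((4, 5)) for m in ("image", "emg", "vio")}
    tensors = {m: Tensor(v) for m, v in feats.items()}
    got = knowledge_sharing_loss(tensors).item()
    mods = ["image", "emg", "vio"]
    expect = 0.0
    for i in range(3):
        for j in range(i + 1, 3):
            expect += np.mean(np.linalg.norm(feats[mods[i]] - feats[mods[j]], axis=1))
    assert got == pytest.approx(expect, rel=1e-6)
    reordered = {m: tensors[m] for m in ("vio", "image", "emg")}
    assert knowledge_sharing_loss(reordered).item() == pytest.approx(got, rel=1e-9)


def test_ks_loss_uses_product_of_positive_normalizers():
    params = SharedSpaceParams(np.random.default_rng(0), {"image": 2, "emg": 2}, 2)
    params.log_norm.data = np.log(np.array([2.0, 3.0], dtype=np.float32))
    feats = {"image": Tensor(np.zeros(2)), "emg": Tensor(np.array([3.0, 4.0]))}
    got = knowledge_sharing_loss(feats, params).item()
    assert got == pytest.approx(5.0 * 2.0 * 3.0, rel=1e-5)


def test_ks_loss_single_modality_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        loss = knowledge_sharing_loss({"emg": Tensor(np.ones(3))})
    assert loss.item() == 0.0


def test_ks_loss_dimension_mismatch_rejected():
    with pytest.raises(DomainError):
        knowledge_sharing_loss({"emg": Tensor(np.ones(3)),
                                "vio": Tensor(np.ones(4))})


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_ks_loss_nonnegative_property(seed):
    rng = np.random.default_rng(seed)
    feats = {m: Tensor(rng.standard_normal((2, 4)) * rng.uniform(0.1, 10))
             for m in ("image", "emg", "vio")}
    assert knowledge_sharing_loss(feats).item() >= 0.0


# --------------------------------------------------------------------- fusion
def test_fusion_output_length_is_sum_of_branch_widths():
    net = FusionNetwork(np.random.default_rng(0), shared_dim=8, widths=(5, 6, 7))
    net.eval()
    feats = {m: RNG.standard_normal((2, 8)).astype(np.float32)
             for m in ("image", "emg", "vio")}
    out = fuse(feats, net)
    assert out.shape == (2, 18)


def test_fusion_single_block_constant_propagation():
    """Identity-weight, zero-bias block on a constant input: pooled output is
    the leaky-ReLU'd constant."""
    branch = FusionBranch(np.random.default_rng(0), in_ch=3, width=3, n_blocks=1)
    w = np.zeros_like(branch.conv0.weight.data)
    for c in range(3):
        w[c, c, 1] = 1.0                      # centre tap passes the channel
    branch.conv0.weight.data = w
    branch.conv0.bias.data[...] = 0.0
    branch.eval()                             # BN uses identity running stats
    const = 0.7
    x = Tensor(np.full((1, 3, 3), const, dtype=np.float32))
    out = branch(x).data
    assert np.allclose(out, const, atol=1e-6)
    xneg = Tensor(np.full((1, 3, 3), -const, dtype=np.float32))
    assert np.allclose(branch(xneg).data, -const * 0.01, atol=1e-6)


def test_fusion_single_block_matches_brute_force_conv_bn_lrelu_mean():
    branch = FusionBranch(np.random.default_rng(5), in_ch=2, width=3, n_blocks=1)
    branch.eval()
    x = RNG.standard_normal((1, 2, 4)).astype(np.float32)
    w, b = branch.conv0.weight.data, branch.conv0.bias.data
    padded = np.pad(x[0], ((0, 0), (1, 1)))
    conv = np.zeros((3, 4))
    for o in range(3):
        for pos in range(4):
            conv[o, pos] = (padded[:, pos:pos + 3] * w[o]).sum() + b[o]
    bn = branch.bn0
    norm = (conv - bn.running_mean[:, None]) / np.sqrt(bn.running_var[:, None] + bn.eps)
    norm = norm * bn.gamma.data[:, None] + bn.beta.data[:, None]
    lrelu = np.where(norm > 0, norm, 0.01 * norm)
    expect = lrelu.mean(axis=1)
    got = branch(Tensor(x)).data[0]
    assert np.allclose(got, expect, atol=1e-5)


def test_fuse_rejects_empty_feature_map():
    net = FusionNetwork(np.random.default_rng(0), shared_dim=4)
    with pytest.raises(DomainError):
        fuse({}, net)


# -------------------------------------------------------------------- decoder
def test_decode_eval_deterministic_and_zero_maps_to_zero():
    dec = Decoder(np.random.default_rng(0), in_dim=6, hidden=5, n_out=4)
    k = RNG.standard_normal(6).astype(np.float32)
    a, b = decode(k, dec), decode(k, dec)
    assert np.array_equal(a, b)
    assert a.shape == (4, 6)
    zero = decode(np.zeros(6, dtype=np.float32), dec)
    assert np.allclose(zero, 0.0, atol=1e-7)       # zero-initialized biases


def test_decode_matches_independent_forward_computation():
    dec = Decoder(np.random.default_rng(4), in_dim=5, hidden=7, n_out=3)
    dec.out_offset = RNG.standard_normal(6).astype(np.float32)
    dec.out_scale = np.abs(RNG.standard_normal(6)).astype(np.float32) + 0.5
    k = RNG.standard_normal(5).astype(np.float32)
    h = dec.fc1.weight.data @ k + dec.fc1.bias.data
    h = (h - dec.bn.running_mean) / np.sqrt(dec.bn.running_var + dec.bn.eps)
    h = h * dec.bn.gamma.data + dec.bn.beta.data
    h = np.maximum(h, 0)
    raw = (dec.head.weight.data @ h + dec.head.bias.data).reshape(3, 6)
    expect = raw * dec.out_scale + dec.out_offset
    assert np.allclose(decode(k, dec), expect, atol=1e-5)


# ------------------------------------------------------------------ pose loss
def test_pose_loss_worked_examples():
    z = np.zeros((1, 1, 6))
    assert pose_loss(z, z).item() == 0.0
    ones = np.ones((1, 1, 6))
    assert pose_loss(ones, z).item() == pytest.approx(1.0)   # (1/6) * 6
    with pytest.raises(DomainError):
        pose_loss(np.zeros((2, 3, 6)), np.zeros((2, 4, 6)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_pose_loss_matches_two_loop_brute_force(seed):
    rng = np.random.default_rng(seed)
    pred = rng.standard_normal((5, 3, 6))
    truth = rng.standard_normal((5, 3, 6))
    got = pose_loss(pred, truth).item()
    total = 0.0
    for b in range(5):
        for t in range(3):
            total += np.mean((pred[b, t] - truth[b, t]) ** 2)
    assert got == pytest.approx(total / 15, rel=1e-9)


def test_rmse_equals_sqrt_of_pose_loss():
    pred = RNG.standard_normal((4, 5, 6))
    truth = RNG.standard_normal((4, 5, 6))
    rmse = np.sqrt(np.mean((pred - truth) ** 2))
    assert rmse == pytest.approx(np.sqrt(pose_loss(pred, truth).item()), rel=1e-9)


def test_pose_loss_masked_restricts_samples():
    pred = np.zeros((2, 3, 6))
    truth = np.ones((2, 3, 6))
    mask = np.zeros((2, 3), dtype=bool)
    mask[0, 0] = True
    assert pose_loss(pred, truth, mask).item() == pytest.approx(1.0)
    with pytest.raises(DomainError):
        pose_loss(pred, truth, np.zeros((2, 3), dtype=bool))


# ------------------------------------------------------------------- pretrain
def test_vio_only_configuration_rejected():
    with pytest.raises(ConfigurationError):
        PoseModelConfig(modalities=("vio",))


def test_pretrain_bookkeeping_and_seeded_determinism(small_cohort):
    cfg = desk_model_config()
    pre = PretrainConfig(epochs_a=1, epochs_b=1, seed=3, val_fraction=0.2)
    model1, log1 = pretrain(small_cohort, cfg, pre)
    model2, log2 = pretrain(small_cohort, cfg, pre)
    # one init row plus one row per stage epoch, all finite
    assert list(log1.stage) == ["init", "A", "B"]
    assert np.isfinite(log1.L_PE.iloc[1:]).all()
    assert log1.L_PE.iloc[-1] == pytest.approx(log2.L_PE.iloc[-1], abs=1e-6)
    s1, s2 = model1.state_dict(), model2.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)


def test_modality_ablation_trains_without_three_modalities(small_cohort):
    cfg = desk_model_config(modalities=("image", "emg"))
    model, log = pretrain(small_cohort, cfg,
                          PretrainConfig(epochs_a=1, epochs_b=1, seed=0))
    assert np.isfinite(log.val_RMSE_deg.iloc[-1])
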