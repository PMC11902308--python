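"""Parameter modulation and episodic adaptation: identity/substitution oracles,
episode sampling contracts, and base-weight freezing."""

import numpy as np
import pytest

from metagait import nn
from metagait.autodiff import Tensor
from metagait.errors import DomainError
from metagait.fusion import PoseModel, pose_loss
from metagait.meta import (Episode, MetaConfig, ModulationParams, TaskDefinition,
                           episode_loss, meta_adapt, meta_train, modulate,
                           sample_episode)
from metagait.pipeline import desk_model_config

RNG = np.random.default_rng(17)


@pytest.fixture(scope="module")
def model(desk_config):
    m = PoseModel(desk_config, seed=1)
    m.eval()
    return m


def _batch(data, idx):
    return {m: v[idx] for m, v in data.arrays.items()}


# ------------------------------------------------------------------ modulation
def test_identity_modulation_is_bit_identical(model, small_data):
    mod = ModulationParams(model)
    view = modulate(model, mod)
    arrays = _batch(small_data, np.arange(4))
    base = model.predict(arrays)
    modded = view.predict(arrays)
    assert np.array_equal(base, modded)


def test_scalar_modulation_arithmetic():
    """W=2, b=1 modulated by gamma_w=3, gamma_b=0.5 gives (6, 1.5)."""
    lin = nn.Linear(np.random.default_rng(0), 1, 1)
    lin.weight.data = np.array([[2.0]], dtype=np.float32)
    lin.bias.data = np.array([1.0], dtype=np.float32)
    gw = Tensor(np.array([3.0], dtype=np.float32))
    gb = Tensor(np.array([0.5], dtype=np.float32))
    eff_w = Tensor(lin.weight.data) * gw.reshape(1, 1)
    eff_b = Tensor(lin.bias.data) + gb
    assert eff_w.data[0, 0] == 6.0
    assert eff_b.data[0] == 1.5
    with nn.substituted({lin.weight: eff_w, lin.bias: eff_b}):
        out = lin(Tensor(np.array([[1.0]], dtype=np.float32))).data
    assert out[0, 0] == pytest.approx(7.5)


def test_random_modulation_equals_explicitly_rebuilt_model(model, small_data, desk_config):
    """Forward under modulation == forward of a model whose tensors were
    substituted by hand (the substitution oracle)."""
    mod = ModulationParams(model)
    rng = np.random.default_rng(5)
    for p in mod.parameters():
        p.data = (p.data + rng.normal(0, 0.2, p.shape)).astype(p.data.dtype)
    view = modulate(model, mod)
    arrays = _batch(small_data, np.arange(3))
    got = view.predict(arrays)

    rebuilt = PoseModel(desk_config, seed=1)
    rebuilt.load_state_dict(model.state_dict())
    from metagait.meta import _modulated_layers
    for (_, layer), (w, gw, b, gb) in zip(_modulated_layers(rebuilt), mod.specs):
        shape = (gw.shape[0],) + (1,) * (w.ndim - 1)
        layer.weight.data = w.data * gw.data.reshape(shape)
        if b is not None:
            layer.bias.data = b.data + gb.data
    rebuilt.eval()
    expect = rebuilt.predict(arrays)
    assert np.allclose(got, expect, atol=1e-5)


def test_modulation_shape_mismatch_rejected(model, desk_config):
    other = PoseModel(desk_model_config(modalities=("image", "emg")), seed=0)
    mod_other = ModulationParams(other)
    with pytest.raises(DomainError):
        modulate(model, mod_other)


# -------------------------------------------------------------------- episodes
def test_sample_episode_disjoint_and_seeded(small_data):
    task = TaskDefinition("subject", int(small_data.subject_ids[0]))
    ep1 = sample_episode(small_data, task, k_shot=5, q_query=10, seed=4)
    ep2 = sample_episode(small_data, task, k_shot=5, q_query=10, seed=4)
    assert len(ep1.support) == 5 and len(ep1.query) == 10
    assert set(ep1.support.clip_keys).isdisjoint(ep1.query.clip_keys)
    assert ep1.support.clip_keys == ep2.support.clip_keys
    assert ep1.query.clip_keys == ep2.query.clip_keys
    assert all(s == task.level for s in ep1.support.subject_ids)


def test_sample_episode_exhaustive_partition(small_data):
    sid = int(small_data.subject_ids[0])
    n = int((small_data.subject_ids == sid).sum())
    ep = sample_episode(small_data, TaskDefinition("subject", sid),
                        k_shot=n - 4, q_query=4, seed=0)
    assert len(ep.support) + len(ep.query) == n
    assert set(ep.support.clip_keys).isdisjoint(ep.query.clip_keys)


def test_sample_episode_insufficient_clips_names_shortfall(small_data):
    sid = int(small_data.subject_ids[0])
    with pytest.raises(DomainError, match="need K\\+Q"):
        sample_episode(small_data, TaskDefinition("subject", sid),
                       k_shot=100, q_query=100, seed=0)


def test_task_definition_validation():
    with pytest.raises(DomainError):
        TaskDefinition("speed", "sprint")
    with pytest.raises(DomainError):
        TaskDefinition("phase", "hover")
    with pytest.raises(DomainError):
        TaskDefinition("terrain", "hill")


# ---------------------------------------------------------------- episode loss
def test_episode_loss_single_clip_equals_pose_loss(model, small_data):
    one = small_data.subset([0])
    got = episode_loss(model, one).item()
    pred = model.predict(one.arrays)
    expect = pose_loss(pred.astype(np.float32), one.targets.astype(np.float32)).item()
    assert got == pytest.approx(expect, rel=1e-5)


def test_episode_loss_is_mean_of_per_clip_losses(model, small_data):
    two = small_data.subset([0, 1])
    l0 = episode_loss(model, small_data.subset([0])).item()
    l1 = episode_loss(model, small_data.subset([1])).item()
    assert episode_loss(model, two).item() == pytest.approx((l0 + l1) / 2, rel=1e-4)


def test_episode_loss_brute_force_oracle(model, small_data):
    sup = small_data.subset(np.arange(4))
    got = episode_loss(model, sup).item()
    pred = model.predict(sup.arrays)
    per_clip = [np.mean((pred[i] - sup.targets[i]) ** 2) for i in range(4)]
    assert got == pytest.approx(np.mean(per_clip), rel=1e-5)


def test_episode_loss_empty_support_rejected(model, small_data):
    with pytest.raises(DomainError):
        episode_loss(model, small_data.subset([]))


# ------------------------------------------------------------------ meta loops
def test_meta_train_zero_steps_zero_lr_preserves_initialization(model, small_data):
    tasks = [TaskDefinition("subject", int(s))
             for s in np.unique(small_data.subject_ids)]
    cfg = MetaConfig(episodes=1, inner_steps=0, inner_lr=0.0, outer_lr=0.0,
                     k_shot=2, q_query=2, seed=0)
    learner, log = meta_train(model, small_data, tasks, cfg)
    for name, p in learner.mod_init.named_parameters():
        if name.startswith("gw"):
            assert np.array_equal(p.data, np.ones_like(p.data)), name
        else:
            assert np.array_equal(p.data, np.zeros_like(p.data)), name
    assert len(log) == 1


def test_meta_train_episode_log_length(model, small_data):
    tasks = [TaskDefinition("subject", int(np.unique(small_data.subject_ids)[0]))]
    cfg = MetaConfig(episodes=3, inner_steps=1, k_shot=2, q_query=2, seed=1)
    learner, log = meta_train(model, small_data, tasks, cfg)
    assert len(log) == 3
    assert np.isfinite(log.query_loss).all()


def test_base_weights_frozen_through_meta_train_and_adapt(model, small_data):
    before = {k: v.copy() for k, v in model.state_dict().items()}
    tasks = [TaskDefinition("subject", int(s))
             for s in np.unique(small_data.subject_ids)]
    cfg = MetaConfig(episodes=2, inner_steps=2, k_shot=2, q_query=2, seed=0)
    learner, _ = meta_train(model, small_data, tasks, cfg)
    adapted = meta_adapt(learner, small_data.subset([0, 1]))
    after = model.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)
    # and the adapted view actually differs from the base in its predictions
    arrays = _batch(small_data, np.arange(2))
    assert not np.array_equal(model.predict(arrays), adapted.predict(arrays))


def test_meta_adapt_zero_steps_matches_initialization_behaviour(model, small_data):
    tasks = [TaskDefinition("subject", int(np.unique(small_data.subject_ids)[0]))]
    cfg = MetaConfig(episodes=1, inner_steps=1, k_shot=2, q_query=2, seed=0)
    learner, _ = meta_train(model, small_data, tasks, cfg)
    sup = small_data.subset([0, 1])
    zero = meta_adapt(learner, sup, steps=0)
    init = learner.init_model()
    arrays = _batch(small_data, np.arange(3))
    assert np.array_equal(zero.predict(arrays), init.predict(arrays))


def test_meta_adapt_deterministic(model, small_data):
    tasks = [TaskDefinition("subject", int(np.unique(small_data.subject_ids)[0]))]
    cfg = MetaConfig(episodes=1, inner_steps=3, k_shot=2, q_query=2, seed=0)
    learner, _ = meta_train(model, small_data, tasks, cfg)
    sup = small_data.subset([0, 1, 2])
    a = meta_adapt(learner, sup)
    b = meta_adapt(learner, sup)
    for pa, pb in zip(a.fast_parameters(), b.fast_parameters()):
        assert np.array_equal(pa.data, pb.data)


def test_meta_train_requires_tasks(model, small_data):
    with pytest.raises(DomainError):
        meta_train(model, small_data, [], MetaConfig(episodes=1))
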