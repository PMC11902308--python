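"""Meta-transfer learning: scale/shift parameter modulation and episodic
few-shot adaptation.

A pretrained pose model is adapted to a new task (a subject, a walking speed,
or a gait phase) without touching its weights: every convolutional/linear
weight W in the encoders, shared-space transforms and fusion network gains a
per-output-channel multiplicative modulation γw and every bias b an additive
γb, so the modulated layer computes (W ⊙ γw) x + (b + γb).  γw initializes to
1 and γb to 0, which reproduces the base model bit-for-bit.  The decoder head
is fully fine-tuned in the inner loop (configurable), since the task-specific
output statistics live there.

Meta-training is episodic: per episode, the shared modulation initialization is
cloned, adapted with a few SGD steps on the N-way K-shot support set under the
episodic loss (mean per-clip MSE), and the initialization is updated from the
query-set gradient (first-order, evaluated at the adapted parameters).
Meta-adaptation runs the same inner loop on a new task's support set only.

Adaptation runs the network in evaluation mode (batch-norm uses pretrained
running statistics): with K as small as 1, batch statistics are degenerate,
while the gradient path through the frozen statistics stays well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .autodiff import Tensor
from .data import ClipArrays
from .errors import DomainError, TrainingError
from .fusion import PoseModel

PHASE_LEVELS = ("stance", "swing")
SPEED_LEVELS = ("slow", "moderate", "fast")


@dataclass(frozen=True)
class TaskDefinition:
    axis: str                    # subject | speed | phase
    level: object                # subject_id, speed class, or phase name

    def __post_init__(self):
        if self.axis not in ("subject", "speed", "phase"):
            raise DomainError(f"unknown task axis {self.axis!r}")
        if self.axis == "speed" and self.level not in SPEED_LEVELS:
            raise DomainError(f"unknown speed level {self.level!r}")
        if self.axis == "phase" and self.level not in PHASE_LEVELS:
            raise DomainError(f"unknown phase level {self.level!r}")


def task_clip_mask(data: ClipArrays, task: TaskDefinition) -> np.ndarray:
    if task.axis == "subject":
        return data.subject_ids == task.level
    if task.axis == "speed":
        return data.speed_classes == task.level
    return np.ones(len(data), dtype=bool)       # phase tasks use every clip


def task_loss_mask(data: ClipArrays, task: TaskDefinition) -> np.ndarray | None:
    """Per-output-sample loss mask for phase tasks (None otherwise)."""
    if task.axis != "phase":
        return None
    return data.stance_mask if task.level == "stance" else ~data.stance_mask


@dataclass
class Episode:
    task: TaskDefinition
    support: ClipArrays
    query: ClipArrays
    n_way: int
    k_shot: int
    q_query: int

    @property
    def support_loss_mask(self):
        return task_loss_mask(self.support, self.task)

    @property
    def query_loss_mask(self):
        return task_loss_mask(self.query, self.task)


def sample_episode(data: ClipArrays, task, k_shot: int, q_query: int,
                   seed: int = 0) -> Episode:
    """Draw disjoint support/query clip sets for a task (N tasks make N ways).

    ``task`` is a TaskDefinition or a list of them (N-way). Sampling is uniform
    without replacement and fully determined by ``seed``.
    """
    tasks = task if isinstance(task, (list, tuple)) else [task]
    if k_shot < 1 or q_query < 1:
        raise DomainError("k_shot and q_query must be >= 1")
    rng = np.random.default_rng(seed)
    sup_idx, qry_idx = [], []
    for t in tasks:
        pool = np.flatnonzero(task_clip_mask(data, t))
        if len(pool) < k_shot + q_query:
            raise DomainError(
                f"task {t}: {len(pool)} clips available, "
                f"need K+Q = {k_shot + q_query}")
        chosen = rng.choice(pool, size=k_shot + q_query, replace=False)
        sup_idx.extend(chosen[:k_shot])
        qry_idx.extend(chosen[k_shot:])
    return Episode(
        task=tasks[0],
        support=data.subset(np.asarray(sup_idx)),
        query=data.subset(np.asarray(qry_idx)),
        n_way=len(tasks),
        k_shot=k_shot,
        q_query=q_query,
    )


# ------------------------------------------------------------------ modulation
_MODULATED_GROUPS = ("enc_image", "enc_emg", "enc_vio", "shared", "fusion")


def _modulated_layers(model: PoseModel):
    """Yield (qualified name, layer) for every conv/linear layer in the
    modulated groups (encoders, shared transforms, fusion)."""
    for group in _MODULATED_GROUPS:
        sub = getattr(model, group, None)
        if sub is None:
            continue
        stack = [(group, sub)]
        while stack:
            prefix, mod = stack.pop()
            for name, child in mod._modules.items():
                stack.append((f"{prefix}.{name}", child))
            if isinstance(mod, (nn.Linear, nn.Conv1d, nn.Conv2d)):
                yield prefix, mod


class ModulationParams(nn.Module):
    """γw (per output channel) and γb (per bias element) for every modulated
    tensor of a PoseModel; identity-initialized (γw=1, γb=0)."""

    def __init__(self, model: PoseModel):
        super().__init__()
        self.specs = []           # (target weight param, γw, target bias or None, γb)
        self.layer_names = []
        for i, (name, layer) in enumerate(_modulated_layers(model)):
            out_ch = layer.weight.shape[0]
            gw = nn.Parameter(np.ones(out_ch))
            setattr(self, f"gw{i}", gw)
            gb = None
            if layer.bias is not None:
                gb = nn.Parameter(np.zeros(layer.bias.shape))
                setattr(self, f"gb{i}", gb)
            self.specs.append((layer.weight, gw, layer.bias, gb))
            self.layer_names.append(name)

    def clone(self) -> "ModulationParams":
        new = object.__new__(ModulationParams)
        nn.Module.__init__(new)
        new.specs = []
        new.layer_names = list(self.layer_names)
        for i, (w, gw, b, gb) in enumerate(self.specs):
            gw2 = nn.Parameter(gw.data.copy())
            setattr(new, f"gw{i}", gw2)
            gb2 = None
            if gb is not None:
                gb2 = nn.Parameter(gb.data.copy())
                setattr(new, f"gb{i}", gb2)
            new.specs.append((w, gw2, b, gb2))
        return new

    def overrides(self) -> dict:
        """Build the substitution map: W -> W⊙γw, b -> b+γb (fresh graph)."""
        table = {}
        for w, gw, b, gb in self.specs:
            shape = (gw.shape[0],) + (1,) * (w.ndim - 1)
            table[w] = Tensor(w.data) * gw.reshape(shape)
            if b is not None and gb is not None:
                table[b] = Tensor(b.data) + gb
        return table

    def matches(self, model: PoseModel) -> bool:
        layers = list(_modulated_layers(model))
        if len(layers) != len(self.specs):
            return False
        return all(l.weight.shape[0] == s[1].shape[0]
                   for (_, l), s in zip(layers, self.specs))


class ModulatedPoseModel:
    """A view of a frozen PoseModel running with modulated parameters (and,
    optionally, a fine-tuned decoder parameter set)."""

    def __init__(self, base: PoseModel, mod: ModulationParams,
                 decoder_params: list | None = None):
        if not mod.matches(base):
            raise DomainError("modulation parameters do not match the model")
        self.base = base
        self.mod = mod
        self.decoder_params = decoder_params
        if decoder_params is not None:
            base_dec = base.decoder.parameters()
            if len(decoder_params) != len(base_dec) or any(
                    p.shape != q.shape for p, q in zip(decoder_params, base_dec)):
                raise DomainError("decoder parameter set does not match the model")

    @property
    def config(self):
        return self.base.config

    def _mapping(self) -> dict:
        table = self.mod.overrides()
        if self.decoder_params is not None:
            for p, q in zip(self.base.decoder.parameters(), self.decoder_params):
                table[p] = q
        return table

    def forward(self, batch: dict, **kw):
        with nn.substituted(self._mapping()):
            return self.base.forward(batch, **kw)

    def __call__(self, batch, **kw):
        return self.forward(batch, **kw)

    def predict(self, batch_arrays: dict, batch_size: int = 32) -> np.ndarray:
        with nn.substituted(self._mapping()):
            return self.base.predict(batch_arrays, batch_size=batch_size)

    def fast_parameters(self) -> list:
        out = self.mod.parameters()
        if self.decoder_params is not None:
            out = out + list(self.decoder_params)
        return out


def modulate(model: PoseModel, mod: ModulationParams,
             decoder_params: list | None = None) -> ModulatedPoseModel:
    """Return a modulated view of ``model``; the base model is unchanged."""
    return ModulatedPoseModel(model, mod, decoder_params)


# --------------------------------------------------------------- episodic loss
def episode_loss(model_like, support: ClipArrays, loss_mask=None) -> Tensor:
    """Episodic loss: mean over the N x K support clips of the per-clip MSE;
    per-clip losses average over that clip's decoded samples."""
    if len(support) == 0:
        raise DomainError("empty support set")
    mods = model_like.config.modalities
    batch = {m: Tensor(support.arrays[m]) for m in mods}
    pred = model_like(batch)
    targets = support.targets.astype(np.float32)
    err = pred - Tensor(targets)
    per_sample = (err * err).mean(axis=-1)          # (B, n_out)
    if loss_mask is None:
        per_clip = per_sample.mean(axis=1)
    else:
        m = np.asarray(loss_mask, dtype=np.float32)
        counts = m.sum(axis=1)
        if np.any(counts == 0):
            raise DomainError("a clip has no samples in the requested phase")
        per_clip = (per_sample * Tensor(m)).sum(axis=1) * Tensor(1.0 / counts)
    return per_clip.mean()


# ----------------------------------------------------------------- meta stages
@dataclass
class MetaConfig:
    episodes: int = 20
    inner_steps: int = 10
    inner_lr: float = 5e-2
    outer_lr: float = 1e-3
    k_shot: int | tuple = 5       # a tuple samples K per episode (mixed-shot)
    q_query: int = 10
    finetune_decoder: bool = True
    prox: float = 2.0             # inner-loop shrinkage toward the init (per 1/K)
    lr_ref_shots: int = 5         # inner lr scales as (K / lr_ref_shots)^1.5
    lr_shot_exponent: float = 1.5
    clip_norm: float = 5.0
    seed: int = 0

    def inner_lr_for(self, k: int) -> float:
        """Adaptation budget proportional to evidence: with Adam inner updates
        the total parameter movement is ~steps x lr, so the learning rate —
        not the loss — must shrink when the support set is small."""
        frac = min(k / self.lr_ref_shots, 1.0) ** self.lr_shot_exponent
        return self.inner_lr * frac


@dataclass
class MetaLearner:
    base: PoseModel
    mod_init: ModulationParams
    decoder_init: list | None
    config: MetaConfig

    def init_model(self) -> ModulatedPoseModel:
        """The meta-learner's zero-step (unadapted-initialization) model."""
        dec = ([nn.Parameter(p.data.copy()) for p in self.decoder_init]
               if self.decoder_init is not None else None)
        return modulate(self.base, self.mod_init.clone(), dec)


def _inner_adapt(base: PoseModel, mod_init: ModulationParams,
                 decoder_init: list | None, support: ClipArrays,
                 loss_mask, steps: int, lr: float,
                 prox: float = 0.0) -> ModulatedPoseModel:
    mod_fast = mod_init.clone()
    dec_fast = ([nn.Parameter(p.data.copy()) for p in decoder_init]
                if decoder_init is not None else None)
    view = modulate(base, mod_fast, dec_fast)
    fast = view.fast_parameters()
    init_values = [p.data.copy() for p in fast]
    base.eval()
    # Adam inner updates: per-parameter steps are bounded by the learning
    # rate irrespective of the raw MSE scale (degrees^2), so a handful of
    # steps can move the head biases by the subject-offset magnitudes.
    # The proximal term shrinks toward the initialization with strength 1/K:
    # the less support data, the more conservative the adaptation — without
    # it, one-shot fine-tuning overfits the support clip's gait phase.
    opt = nn.Adam(fast, lr=lr)
    prox_scale = prox / max(len(support), 1)
    for _ in range(steps):
        loss = episode_loss(view, support, loss_mask)
        if prox_scale > 0:
            for p, p0 in zip(fast, init_values):
                d = p - Tensor(p0)
                loss = loss + (d * d).sum() * prox_scale
        if not np.isfinite(loss.item()):
            raise TrainingError("non-finite inner-loop loss")
        opt.zero_grad()
        loss.backward()
        opt.step()
    return view


def meta_train(pretrained: PoseModel, data: ClipArrays,
               tasks: list, config: MetaConfig | None = None) -> tuple:
    """Episodic meta-training of the modulation initialization.

    Returns (MetaLearner, episode log).  The pretrained model's own parameters
    are never updated; only the shared modulation initialization (and, if
    configured, the decoder-head initialization) moves.
    """
    config = config or MetaConfig()
    if not tasks:
        raise DomainError("meta_train needs at least one task")
    rng = np.random.default_rng(config.seed)
    mod_init = ModulationParams(pretrained)
    decoder_init = ([nn.Parameter(p.data.copy())
                     for p in pretrained.decoder.parameters()]
                    if config.finetune_decoder else None)
    outer_params = mod_init.parameters() + (decoder_init or [])
    opt = nn.Adam(outer_params, lr=config.outer_lr)
    pretrained.eval()
    rows = []
    k_choices = (config.k_shot if isinstance(config.k_shot, (tuple, list))
                 else (config.k_shot,))
    for ep in range(config.episodes):
        task = tasks[int(rng.integers(len(tasks)))]
        k = int(k_choices[int(rng.integers(len(k_choices)))])
        episode = sample_episode(data, task, k, config.q_query,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        adapted = _inner_adapt(pretrained, mod_init, decoder_init,
                               episode.support, episode.support_loss_mask,
                               config.inner_steps, config.inner_lr_for(k),
                               config.prox)
        fast = adapted.fast_parameters()
        for p in fast:
            p.zero_grad()
        q_loss = episode_loss(adapted, episode.query, episode.query_loss_mask)
        if not np.isfinite(q_loss.item()):
            raise TrainingError(f"non-finite query loss at episode {ep}")
        q_loss.backward()
        # first-order outer update: apply the query gradient at the adapted
        # parameters to the shared initialization
        for init_p, fast_p in zip(outer_params, fast):
            init_p.grad = fast_p.grad
        nn.clip_grad_norm(outer_params, config.clip_norm)
        opt.step()
        rows.append(dict(episode=ep, task_axis=task.axis, task_level=str(task.level),
                         k_shot=k, query_loss=q_loss.item(),
                         query_rmse_deg=float(np.sqrt(q_loss.item()))))
    learner = MetaLearner(pretrained, mod_init, decoder_init, config)
    return learner, pd.DataFrame(rows)


def meta_adapt(meta: MetaLearner, support: ClipArrays,
               steps: int | None = None, lr: float | None = None,
               loss_mask=None) -> ModulatedPoseModel:
    """Fine-tune the meta-learned initialization on a new task's support set.

    Only modulation (and optionally decoder-head) parameters move; the
    pretrained base stays frozen.  Deterministic in (meta, support).
    """
    if len(support) == 0:
        raise DomainError("empty support set")
    return _inner_adapt(
        meta.base, meta.mod_init, meta.decoder_init, support, loss_mask,
        meta.config.inner_steps if steps is None else steps,
        meta.config.inner_lr_for(len(support)) if lr is None else lr,
        meta.config.prox,
    )
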