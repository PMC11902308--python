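"""Knowledge-sharing alignment, multi-branch fusion, decoding, and pretraining.

The pose-estimation network is: per-modality encoders producing features r_m;
per-modality affine transforms f_m mapping every modality into one shared
D-dimensional space (r̃_m = f_m(r_m)); a pairwise alignment loss

    L_KS = sum over unordered modality pairs (k, t) of m_k * m_t * ||r̃_k − r̃_t||_2,

with trainable positive per-modality normalizers m_m (parameterized as exp of a
free scalar); a three-branch convolutional fusion network over the stacked
aligned features whose branch outputs are globally average-pooled and
concatenated into the fused feature k; and a decoder regressing the six
lower-limb joint angles (L/R hip, knee, ankle, degrees) at ``n_out`` uniformly
spaced time points of the clip.  The pose loss is per-sample mean squared error
over the six angles, averaged over samples (so pooled RMSE = sqrt(L_PE)).

In the non-knowledge-sharing (nKS) ablation the transforms and L_KS are removed
and the raw encoder features are plainly concatenated into k.

Pretraining runs in two stages: stage A trains the whole network on
L_KS + λ·L_PE (the pose term keeps the alignment objective away from its
trivial constant-feature optimum); stage B freezes encoders and transforms and
trains fusion + decoder on L_PE alone, honoring the separately-trained
knowledge-transfer design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .autodiff import Tensor, concat, no_grad
from .encoders import (ImageEncoder, ImageEncoderConfig, SequenceEncoder,
                       default_emg_config, default_vio_config)
from .errors import ConfigurationError, DomainError, TrainingError
from .synthetic import CohortDataset

MODALITY_ORDER = ("image", "emg", "vio")


# ------------------------------------------------------------------ transforms
class ModalityTransform(nn.Module):
    """Affine map into the shared space, with an optional nonlinearity."""

    def __init__(self, rng, in_dim: int, out_dim: int, activation: str = "linear"):
        super().__init__()
        self.linear = nn.Linear(rng, in_dim, out_dim)
        if activation not in ("linear", "tanh", "leaky_relu"):
            raise ConfigurationError(f"unknown activation {activation!r}")
        self.activation = activation

    def identity_init(self):
        o, i = self.linear.weight.shape
        if o != i:
            raise ConfigurationError("identity init requires square transform")
        self.linear.weight.data = np.eye(o, dtype=self.linear.weight.data.dtype)
        self.linear.bias.data[...] = 0.0
        return self

    def forward(self, x: Tensor) -> Tensor:
        h = self.linear(x)
        if self.activation == "tanh":
            return h.tanh()
        if self.activation == "leaky_relu":
            return h.leaky_relu(0.01)
        return h


class SharedSpaceParams(nn.Module):
    """Per-modality transforms plus trainable positive normalizers m_m."""

    def __init__(self, rng, in_dims: dict, shared_dim: int,
                 activation: str = "linear"):
        super().__init__()
        self.modalities = tuple(in_dims)
        for m, d in in_dims.items():
            setattr(self, f"transform_{m}",
                    ModalityTransform(rng, d, shared_dim, activation))
        # normalizers parameterized as exp(log_m) so they stay positive
        self.log_norm = nn.Parameter(np.zeros(len(in_dims)))
        self.shared_dim = shared_dim

    def transform(self, modality: str, r: Tensor) -> Tensor:
        if modality not in self.modalities:
            raise DomainError(f"no transform for modality {modality!r}")
        return getattr(self, f"transform_{modality}")(r)

    def normalizer(self, modality: str) -> Tensor:
        i = self.modalities.index(modality)
        return nn.P(self.log_norm)[i].exp()


def transform_feature(r, params: SharedSpaceParams, modality: str) -> Tensor:
    """Map one encoded feature r_m into the shared space (r̃_m)."""
    r = r if isinstance(r, Tensor) else Tensor(np.asarray(r, dtype=np.float32))
    return params.transform(modality, r)


def knowledge_sharing_loss(features: dict, params: SharedSpaceParams | None = None,
                           eps: float = 1e-12) -> Tensor:
    """Pairwise Euclidean alignment loss over the aligned features.

    ``features`` maps modality -> (B, D) Tensor (or (D,) for a single clip).
    Per-clip distances are averaged over the batch; the pair normalizer is the
    product of the two per-modality normalizers (1 if ``params`` is None).
    Returns 0 with a single modality.
    """
    mods = sorted(features)
    if len(mods) < 2:
        import warnings
        warnings.warn("knowledge_sharing_loss needs >= 2 modalities; returning 0",
                      stacklevel=2)
        return Tensor(np.zeros(()))
    dims = {m: features[m].shape[-1] for m in mods}
    if len(set(dims.values())) != 1:
        raise DomainError(f"aligned feature dims differ: {dims}")
    total = None
    for i, k in enumerate(mods):
        for t in mods[i + 1:]:
            diff = features[k] - features[t]
            if diff.ndim == 1:
                diff = diff.reshape(1, -1)
            dist = ((diff * diff).sum(axis=1) + eps).sqrt().mean()
            if params is not None:
                dist = dist * params.normalizer(k) * params.normalizer(t)
            total = dist if total is None else total + dist
    return total


# --------------------------------------------------------------------- fusion
class FusionBranch(nn.Module):
    def __init__(self, rng, in_ch: int, width: int, n_blocks: int):
        super().__init__()
        self.n_blocks = n_blocks
        ch = in_ch
        for i in range(n_blocks):
            setattr(self, f"conv{i}", nn.Conv1d(rng, ch, width, 3, pad=1))
            setattr(self, f"bn{i}", nn.BatchNorm(width))
            ch = width

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for i in range(self.n_blocks):
            h = getattr(self, f"bn{i}")(getattr(self, f"conv{i}")(h)).leaky_relu(0.01)
        return h.mean(axis=2)                       # global average pool


class FusionNetwork(nn.Module):
    """Three convolutional branches (1, 2, 3 blocks) over the stacked aligned
    features, treated as a length-``n_modalities`` sequence with D channels."""

    def __init__(self, rng, shared_dim: int, widths: tuple = (32, 32, 32)):
        super().__init__()
        self.widths = tuple(widths)
        for b, w in enumerate(self.widths, start=1):
            setattr(self, f"branch{b}", FusionBranch(rng, shared_dim, w, b))
        self.output_dim = sum(self.widths)

    def forward(self, aligned: dict) -> Tensor:
        if not aligned:
            raise DomainError("fuse() needs at least one modality feature")
        mods = [m for m in MODALITY_ORDER if m in aligned]
        # (B, D) per modality -> (B, D, n_mods)
        seq = concat([aligned[m].reshape(*aligned[m].shape, 1) for m in mods], axis=2)
        outs = [getattr(self, f"branch{b}")(seq) for b in range(1, len(self.widths) + 1)]
        return concat(outs, axis=1)


def fuse(features: dict, network: FusionNetwork) -> Tensor:
    """Fused feature k from a modality->feature map (single clip or batch)."""
    lifted = {}
    for m, v in features.items():
        v = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float32))
        lifted[m] = v.reshape(1, -1) if v.ndim == 1 else v
    return network(lifted)


# -------------------------------------------------------------------- decoder
class Decoder(nn.Module):
    """Fused feature -> joint-angle trajectory (n_out time points x 6 angles).

    The regression head works on standardized angles; per-joint output offset
    and scale buffers (set from the pretraining targets) map back to degrees,
    keeping optimization well-conditioned regardless of joint ranges.
    """

    def __init__(self, rng, in_dim: int, hidden: int = 64, n_out: int = 25,
                 dropout: float = 0.1, dropout_seed: int = 0):
        super().__init__()
        self.fc1 = nn.Linear(rng, in_dim, hidden)
        self.bn = nn.BatchNorm(hidden)
        self.drop = nn.Dropout(dropout, seed=dropout_seed)
        self.head = nn.Linear(rng, hidden, 6 * n_out)
        self.n_out = n_out
        self.out_offset = np.zeros(6, dtype=nn.DTYPE)
        self.out_scale = np.ones(6, dtype=nn.DTYPE)
        object.__setattr__(self, "_buffer_names", ("out_offset", "out_scale"))

    def set_output_stats(self, targets: np.ndarray):
        """Fix the degree-scale mapping from (N, T, 6) pretraining targets."""
        flat = targets.reshape(-1, 6)
        self.out_offset = flat.mean(axis=0).astype(nn.DTYPE)
        self.out_scale = np.maximum(flat.std(axis=0), 1e-3).astype(nn.DTYPE)

    def forward(self, k: Tensor) -> Tensor:
        h = self.drop(self.bn(self.fc1(k)).relu())
        out = self.head(h)
        out = out.reshape(out.shape[0], self.n_out, 6)
        return out * Tensor(self.out_scale) + Tensor(self.out_offset)


def decode(k, decoder: Decoder) -> np.ndarray:
    """Evaluation-mode decoding of a fused feature (single clip or batch)."""
    k = k if isinstance(k, Tensor) else Tensor(np.asarray(k, dtype=np.float32))
    if k.ndim == 1:
        k = k.reshape(1, -1)
    decoder.eval()
    with no_grad():
        out = decoder(k)
    return out.data[0] if out.shape[0] == 1 else out.data


# --------------------------------------------------------------------- losses
def pose_loss(pred, truth, mask=None) -> Tensor:
    """Mean squared error: per sample, (1/6)·sum over the 6 angles of the squared
    residual; averaged over samples (optionally restricted by a boolean mask
    over samples).  sqrt(pose_loss) is the pooled RMSE."""
    pred = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=np.float64))
    truth = truth.data if isinstance(truth, Tensor) else np.asarray(truth)
    if pred.shape != truth.shape:
        raise DomainError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    err = pred - Tensor(truth)
    per_sample = (err * err).mean(axis=-1)
    if mask is None:
        return per_sample.mean()
    mask = np.asarray(mask, dtype=per_sample.dtype)
    if mask.shape != per_sample.shape:
        raise DomainError(f"mask shape {mask.shape} != sample shape {per_sample.shape}")
    denom = float(mask.sum())
    if denom == 0:
        raise DomainError("mask selects no samples")
    return (per_sample * Tensor(mask)).sum() * (1.0 / denom)


# ------------------------------------------------------------------ the model
@dataclass
class PoseModelConfig:
    modalities: tuple = ("image", "emg", "vio")
    use_ks: bool = True
    shared_dim: int = 64
    branch_widths: tuple = (32, 32, 32)
    decoder_hidden: int = 64
    n_out: int = 25               # decoded time points per clip
    dropout: float = 0.1
    transform_activation: str = "linear"
    image: ImageEncoderConfig = field(default_factory=ImageEncoderConfig)
    emg_kwargs: dict = field(default_factory=dict)
    vio_kwargs: dict = field(default_factory=dict)
    input_hw: int = 64

    def __post_init__(self):
        if not self.modalities:
            raise ConfigurationError("at least one modality required")
        if tuple(self.modalities) == ("vio",):
            raise ConfigurationError(
                "VIO-only configuration is rejected: VIO lacks spatial context "
                "for pose estimation")
        for m in self.modalities:
            if m not in MODALITY_ORDER:
                raise ConfigurationError(f"unknown modality {m!r}")


class PoseModel(nn.Module):
    """Encoders + shared-space transforms + fusion + decoder."""

    def __init__(self, config: PoseModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        dims = {}
        if "image" in config.modalities:
            self.enc_image = ImageEncoder(rng, config.image, config.input_hw)
            dims["image"] = self.enc_image.output_dim
        if "emg" in config.modalities:
            self.enc_emg = SequenceEncoder(rng, default_emg_config(**config.emg_kwargs), "emg")
            dims["emg"] = self.enc_emg.output_dim
        if "vio" in config.modalities:
            self.enc_vio = SequenceEncoder(rng, default_vio_config(**config.vio_kwargs), "vio")
            dims["vio"] = self.enc_vio.output_dim
        self.feature_dims = dims
        if config.use_ks:
            self.shared = SharedSpaceParams(rng, dims, config.shared_dim,
                                            config.transform_activation)
            self.fusion = FusionNetwork(rng, config.shared_dim, config.branch_widths)
            fused_dim = self.fusion.output_dim
        else:
            self.shared = None
            self.fusion = None
            fused_dim = sum(dims.values())
        self.decoder = Decoder(rng, fused_dim, config.decoder_hidden,
                               config.n_out, config.dropout,
                               dropout_seed=int(rng.integers(0, 2**31 - 1)))

    # --------------------------------------------------------------- encoders
    def encoder(self, modality: str) -> nn.Module:
        return getattr(self, f"enc_{modality}")

    def encode(self, batch: dict) -> dict:
        feats = {}
        for m in self.config.modalities:
            x = batch[m]
            x = x if isinstance(x, Tensor) else Tensor(x)
            feats[m] = self.encoder(m)(x)
        return feats

    def forward(self, batch: dict, return_features: bool = False):
        feats = self.encode(batch)
        if self.config.use_ks:
            aligned = {m: self.shared.transform(m, r) for m, r in feats.items()}
            k = self.fusion(aligned)
        else:
            aligned = feats
            k = concat([feats[m] for m in MODALITY_ORDER if m in feats], axis=1)
        pred = self.decoder(k)
        if return_features:
            return pred, feats, aligned
        return pred

    def predict(self, batch_arrays: dict, batch_size: int = 32) -> np.ndarray:
        """Evaluation-mode predictions (N, n_out, 6) for preprocessed arrays."""
        self.eval()
        n = len(next(iter(batch_arrays.values())))
        outs = []
        with no_grad():
            for i in range(0, n, batch_size):
                sub = {m: Tensor(v[i:i + batch_size]) for m, v in batch_arrays.items()
                       if m in self.config.modalities}
                outs.append(self.forward(sub).data)
        return np.concatenate(outs, axis=0)

    # ------------------------------------------------------------- group views
    def encoder_transform_params(self) -> list:
        names = [f"enc_{m}" for m in self.config.modalities]
        if self.shared is not None:
            names.append("shared")
        out = []
        for n in names:
            out.extend(getattr(self, n).parameters())
        return out

    def fusion_decoder_params(self) -> list:
        out = list(self.decoder.parameters())
        if self.fusion is not None:
            out.extend(self.fusion.parameters())
        return out


# ----------------------------------------------------------------- pretraining
@dataclass
class PretrainConfig:
    epochs_a: int = 6             # joint stage: L_KS + lambda_pe * L_PE
    epochs_b: int = 6             # fusion+decoder stage: L_PE only
    batch_size: int = 16
    lr: float = 1e-3
    lambda_pe: float = 0.1
    clip_norm: float = 5.0
    val_fraction: float = 0.15
    seed: int = 0


def _epoch_batches(rng, n: int, batch_size: int):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _batch_tensors(data, idx, modalities) -> tuple:
    batch = {m: Tensor(data.arrays[m][idx]) for m in modalities}
    targets = data.targets[idx].astype(np.float32)
    return batch, targets


def evaluate_rmse(model: PoseModel, data) -> float:
    """Pooled validation RMSE in degrees over all joints and samples."""
    pred = model.predict(data.arrays)
    return float(np.sqrt(np.mean((pred - data.targets) ** 2)))


def pretrain(dataset, model_config: PoseModelConfig,
             config: PretrainConfig | None = None,
             val_data=None) -> tuple:
    """Train a PoseModel on a cohort (or clip list). Returns (model, log).

    The log is a DataFrame with per-epoch mean L_PE, L_KS and validation RMSE;
    its first row records the untrained model ("init" stage).
    """
    from .data import prepare_clips

    config = config or PretrainConfig()
    if isinstance(dataset, CohortDataset):
        clips = dataset.clips()
    else:
        clips = list(dataset)
    if not clips:
        raise DomainError("empty dataset")
    data = prepare_clips(clips, model_config)
    if val_data is None and config.val_fraction > 0 and len(data) >= 4:
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(data))
        n_val = max(1, int(round(config.val_fraction * len(data))))
        val_data = data.subset(order[:n_val])
        data = data.subset(order[n_val:])
    return pretrain_arrays(data, model_config, config, val_data=val_data)


def pretrain_arrays(data, model_config: PoseModelConfig,
                    config: PretrainConfig | None = None,
                    val_data=None) -> tuple:
    """Two-stage pretraining on already-prepared clip arrays."""
    config = config or PretrainConfig()
    if len(data) == 0:
        raise DomainError("empty dataset")
    rng = np.random.default_rng(config.seed)
    model = PoseModel(model_config, seed=config.seed)
    log_rows = []

    best = {"rmse": np.inf, "state": None}

    def val_rmse():
        if val_data is None:
            return np.nan
        r = evaluate_rmse(model, val_data)
        if r < best["rmse"]:
            best["rmse"] = r
            best["state"] = model.state_dict()
        return r

    # epoch-0 reference: the freshly initialized model, before anything is
    # fit from the training data (including the output standardization);
    # bypasses best-checkpoint tracking so training is always preferred
    init_rmse = evaluate_rmse(model, val_data) if val_data is not None else np.nan
    log_rows.append(dict(stage="init", epoch=0, L_PE=np.nan, L_KS=np.nan,
                         val_RMSE_deg=init_rmse))
    model.decoder.set_output_stats(data.targets)

    def run_stage(stage: str, params, epochs: int, with_ks: bool, lam: float):
        opt = nn.Adam(params, lr=config.lr)
        for ep in range(epochs):
            model.train()
            pe_sum, ks_sum, nb = 0.0, 0.0, 0
            for idx in _epoch_batches(rng, len(data), config.batch_size):
                batch, targets = _batch_tensors(data, idx, model_config.modalities)
                pred, feats, aligned = model(batch, return_features=True)
                l_pe = pose_loss(pred, targets)
                if with_ks and model.config.use_ks:
                    l_ks = knowledge_sharing_loss(aligned, model.shared)
                    loss = l_ks + lam * l_pe
                else:
                    l_ks = Tensor(np.zeros(()))
                    loss = l_pe
                if not np.isfinite(loss.item()):
                    raise TrainingError(
                        f"non-finite loss in stage {stage} epoch {ep}: "
                        f"L_PE={l_pe.item()}, L_KS={l_ks.item()}")
                opt.zero_grad()
                loss.backward()
                nn.clip_grad_norm(opt.params, config.clip_norm)
                opt.step()
                pe_sum += l_pe.item()
                ks_sum += l_ks.item()
                nb += 1
            log_rows.append(dict(stage=stage, epoch=ep, L_PE=pe_sum / nb,
                                 L_KS=ks_sum / nb, val_RMSE_deg=val_rmse()))

    if model_config.use_ks:
        run_stage("A", model.parameters(), config.epochs_a, True, config.lambda_pe)
        run_stage("B", model.fusion_decoder_params(), config.epochs_b, False, 0.0)
    else:
        run_stage("nKS", model.parameters(),
                  config.epochs_a + config.epochs_b, False, 0.0)
    # keep the best-validation checkpoint (the init-stage snapshot is never
    # stored, so an epoch of training is always preferred over no training)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    return model, pd.DataFrame(log_rows)


# ---------------------------------------------------------------- persistence
def pose_config_to_dict(cfg: PoseModelConfig) -> dict:
    from dataclasses import asdict
    d = asdict(cfg)
    d["modalities"] = list(cfg.modalities)
    d["branch_widths"] = list(cfg.branch_widths)
    d["image"]["widths"] = list(cfg.image.widths)
    return d


def pose_config_from_dict(d: dict) -> PoseModelConfig:
    d = dict(d)
    img = dict(d.pop("image"))
    img["widths"] = tuple(img["widths"])
    d["image"] = ImageEncoderConfig(**img)
    d["modalities"] = tuple(d["modalities"])
    d["branch_widths"] = tuple(d["branch_widths"])
    return PoseModelConfig(**d)


def save_pose_model(model: PoseModel, path, extra: dict | None = None):
    import json as _json
    meta = {"pose_config": pose_config_to_dict(model.config)}
    meta.update(extra or {})
    model.save(path, extra=meta)


def load_pose_model(path) -> tuple:
    """Load a PoseModel checkpoint -> (model, metadata dict)."""
    import json as _json
    with np.load(path) as z:
        meta = _json.loads(bytes(z["__meta__"]).decode())
    cfg = pose_config_from_dict(meta["pose_config"])
    model = PoseModel(cfg, seed=0)
    meta2 = model.load(path)
    model.eval()
    return model, meta2
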