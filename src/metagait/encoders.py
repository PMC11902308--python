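"""Per-modality feature encoders.

The image stream is encoded by a CBAM-ResNet12: four residual stages, each
three 3x3 convolutions with batch norm, a convolutional block attention module
(channel attention followed by spatial attention), and 2x2 max pooling.  The
sEMG and VIO streams are encoded by pre-norm transformer encoders over patched
token sequences with fixed sinusoidal positional encodings; the clip feature is
the mean over output tokens.

Raw-stream preprocessing (frame subsampling, EMG rectification/decimation,
patching) lives here too, so an encoder consumes a ``ModalityStream`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concat, maxpool2d
from .errors import ConfigurationError, DomainError
from .synthetic import ModalityStream


# ------------------------------------------------------------------- configs
@dataclass
class ImageEncoderConfig:
    frames: int = 8               # frames uniformly subsampled per clip
    spatial_stride: int = 1       # pixel decimation before encoding
    widths: tuple = (16, 32, 64, 128)
    reduction: int = 8            # CBAM channel-attention bottleneck ratio
    spatial_kernel: int = 7       # CBAM spatial-attention kernel
    in_channels: int = 3


@dataclass
class SequenceEncoderConfig:
    in_channels: int = 6
    patch: int = 50               # samples per token
    downsample: int = 1           # decimation factor before patching
    rectify: bool = False         # |x| + moving-average (EMG envelope proxy)
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 128
    max_tokens: int = 256
    positional: bool = True


def default_emg_config(**kw) -> SequenceEncoderConfig:
    # ~1111 Hz decimated to ~111 Hz, 50-sample tokens
    return SequenceEncoderConfig(in_channels=6, patch=50, downsample=10,
                                 rectify=True, **kw)


def default_vio_config(**kw) -> SequenceEncoderConfig:
    return SequenceEncoderConfig(in_channels=7, patch=20, downsample=1,
                                 rectify=False, **kw)


# ---------------------------------------------------------------------- CBAM
class ChannelAttention(nn.Module):
    """Squeeze channel descriptors (avg & max pool) through a shared two-layer
    bottleneck; scale channels by sigmoid(MLP(avg) + MLP(max))."""

    def __init__(self, rng, channels: int, reduction: int = 8):
        super().__init__()
        if reduction <= 0:
            raise ConfigurationError("reduction must be positive")
        if channels < reduction:
            raise ConfigurationError(
                f"channels ({channels}) must be >= reduction ({reduction})")
        hidden = channels // reduction
        self.fc1 = nn.Linear(rng, channels, hidden, bias=False)
        self.fc2 = nn.Linear(rng, hidden, channels, bias=False)

    def weights(self, x: Tensor) -> Tensor:
        # x: (B, C, H, W) -> (B, C)
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=3).max(axis=2)
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        return x * self.weights(x).reshape(b, c, 1, 1)


class SpatialAttention(nn.Module):
    """Scale positions by a sigmoid map convolved from channel-wise mean/max."""

    def __init__(self, rng, kernel: int = 7):
        super().__init__()
        if kernel % 2 == 0:
            raise ConfigurationError("spatial-attention kernel must be odd")
        self.conv = nn.Conv2d(rng, 2, 1, kernel, pad=kernel // 2)

    def weights(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.weights(x)


class CBAM(nn.Module):
    def __init__(self, rng, channels: int, reduction: int = 8, kernel: int = 7):
        super().__init__()
        self.channel = ChannelAttention(rng, channels, reduction)
        self.spatial = SpatialAttention(rng, kernel)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


class ResidualBlock(nn.Module):
    """Three conv-BN layers with an identity/projection skip, then CBAM and
    2x2 max pooling (one CBAM-ResNet12 stage)."""

    def __init__(self, rng, in_ch: int, out_ch: int, reduction: int, kernel: int):
        super().__init__()
        self.c1 = nn.Conv2d(rng, in_ch, out_ch, 3, pad=1, bias=False)
        self.b1 = nn.BatchNorm(out_ch)
        self.c2 = nn.Conv2d(rng, out_ch, out_ch, 3, pad=1, bias=False)
        self.b2 = nn.BatchNorm(out_ch)
        self.c3 = nn.Conv2d(rng, out_ch, out_ch, 3, pad=1, bias=False)
        self.b3 = nn.BatchNorm(out_ch)
        self.proj = nn.Conv2d(rng, in_ch, out_ch, 1, bias=False)
        self.bproj = nn.BatchNorm(out_ch)
        self.cbam = CBAM(rng, out_ch, reduction, kernel)

    def forward(self, x: Tensor) -> Tensor:
        h = self.b1(self.c1(x)).relu()
        h = self.b2(self.c2(h)).relu()
        h = self.b3(self.c3(h))
        skip = self.bproj(self.proj(x))
        h = (h + skip).relu()
        h = self.cbam(h)
        return maxpool2d(h, 2)


class ImageEncoder(nn.Module):
    """CBAM-ResNet12 over subsampled clip frames; frame features are mean-pooled
    into one clip-level vector r_i."""

    modality = "image"

    def __init__(self, rng, config: ImageEncoderConfig, input_hw: int):
        super().__init__()
        self.config = config
        hw = -(-input_hw // config.spatial_stride)   # ceil division
        if hw // 16 < 1:
            raise ConfigurationError(
                f"input {hw}x{hw} too small for 4 pooling stages")
        chans = (config.in_channels,) + tuple(config.widths)
        for i in range(4):
            setattr(self, f"block{i}",
                    ResidualBlock(rng, chans[i], chans[i + 1],
                                  config.reduction, config.spatial_kernel))
        self.output_dim = config.widths[-1]

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, F, C, H, W) -> (B, output_dim)
        b, f = x.shape[0], x.shape[1]
        h = x.reshape(b * f, *x.shape[2:])
        for i in range(4):
            h = getattr(self, f"block{i}")(h)
        feat = h.mean(axis=(2, 3))                    # global average pool
        return feat.reshape(b, f, self.output_dim).mean(axis=1)

    def preprocess(self, stream: ModalityStream) -> np.ndarray:
        if stream.modality != "image":
            raise DomainError(f"expected image stream, got {stream.modality}")
        return preprocess_image(stream.samples, self.config.frames,
                                self.config.spatial_stride)


class SequenceEncoder(nn.Module):
    """Pre-norm transformer over patched tokens with sinusoidal positions."""

    def __init__(self, rng, config: SequenceEncoderConfig, modality: str):
        super().__init__()
        self.config = config
        self.modality = modality
        d_in = config.patch * config.in_channels
        self.embed = nn.Linear(rng, d_in, config.d_model)
        for i in range(config.n_layers):
            setattr(self, f"layer{i}",
                    nn.TransformerEncoderLayer(rng, config.d_model,
                                               config.n_heads, config.d_ff))
        self.output_dim = config.d_model

    def forward(self, tokens: Tensor, positional: bool | None = None) -> Tensor:
        # tokens: (B, T, patch*channels) -> (B, d_model)
        if tokens.shape[1] == 0:
            raise DomainError("empty token sequence")
        x = self.embed(tokens)
        use_pos = self.config.positional if positional is None else positional
        if use_pos:
            x = x + Tensor(nn.sinusoidal_positions(x.shape[1], x.shape[2]))
        for i in range(self.config.n_layers):
            x = getattr(self, f"layer{i}")(x)
        return x.mean(axis=1)

    def preprocess(self, stream: ModalityStream) -> np.ndarray:
        if stream.modality != self.modality:
            raise DomainError(
                f"expected {self.modality} stream, got {stream.modality}")
        return preprocess_sequence(stream.samples, self.config)


# ------------------------------------------------------------- preprocessing
def preprocess_image(samples: np.ndarray, frames: int, spatial_stride: int = 1
                     ) -> np.ndarray:
    """(T, H, W, C) uint8 -> (frames, C, H', W') float32 in [0, 1]."""
    t = samples.shape[0]
    if t == 0:
        raise DomainError("empty image stream")
    idx = np.round(np.linspace(0, t - 1, frames)).astype(int)
    sub = samples[idx, ::spatial_stride, ::spatial_stride]
    return (sub.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


def preprocess_sequence(samples: np.ndarray, config: SequenceEncoderConfig
                        ) -> np.ndarray:
    """(T, D) -> (n_tokens, patch*D) float32 tokens."""
    x = np.asarray(samples, dtype=np.float32)
    if x.shape[0] == 0:
        raise DomainError("empty sequence stream")
    ds = config.downsample
    if config.rectify:
        x = np.abs(x)
    if ds > 1:
        n = (x.shape[0] // ds) * ds
        x = x[:n].reshape(-1, ds, x.shape[1]).mean(axis=1)
    n_tok = min(x.shape[0] // config.patch, config.max_tokens)
    if n_tok == 0:
        raise DomainError("sequence shorter than one patch")
    x = x[: n_tok * config.patch].reshape(n_tok, config.patch * x.shape[1])
    return x


# ------------------------------------------------------ functional interface
def encode_image(stream: ModalityStream, encoder: ImageEncoder) -> np.ndarray:
    """Clip-level image feature r_i for one stream (evaluation mode)."""
    x = encoder.preprocess(stream)[None]
    encoder.eval()
    from .autodiff import no_grad
    with no_grad():
        return encoder(Tensor(x)).data[0]


def encode_sequence(stream: ModalityStream, encoder: SequenceEncoder) -> np.ndarray:
    """Clip-level sequence feature r_e / r_v for one stream (evaluation mode)."""
    x = encoder.preprocess(stream)[None]
    encoder.eval()
    from .autodiff import no_grad
    with no_grad():
        return encoder(Tensor(x)).data[0]
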