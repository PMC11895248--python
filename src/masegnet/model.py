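"""The CBAM-AG-UNet: a U-shaped encoder-decoder with three attention
mechanisms.

* Channel attention: global average- and max-pooled channel descriptors
  pass through a shared two-layer perceptron (reduction ratio r), are
  summed and squashed by a sigmoid to a per-channel weight
  M_c in (0,1)^{C x 1 x 1}.
* Spatial attention: channel-wise mean and max maps are concatenated and
  convolved with a single 7x7 kernel, giving M_s in (0,1)^{1 x H x W}.
* CBAM applies the two sequentially, channel first:
  F' = M_c(F) * F, F'' = M_s(F') * F'.
* Attention gates on the skip connections: the skip features and the
  coarser decoder-side gating signal are projected to a common channel
  width by 1x1 convolutions, summed (after bilinear resampling of the
  gating signal to the skip grid), ReLU-ed, projected to one channel and
  squashed to alpha in (0,1)^{1 x H x W}; the skip is scaled by alpha
  before fusion.

Each encoder step is double 3x3 conv + ReLU followed by CBAM and a 2x2
max-pool; each decoder step is the "three-fold" block: attention-gate the
skip, upsample the decoder signal with a 2x2 transposed convolution,
concatenate, double 3x3 conv + ReLU, then CBAM.  A 1x1 convolution with a
sigmoid produces the per-pixel lesion probability map.  Channel widths
double per downsampling stage; the default (base 32, depth 4) gives a
512-filter bottleneck.  ``use_cbam`` / ``use_ag`` toggles reduce the
network to its ablation variants, down to a plain U-Net.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from masegnet import nn
from masegnet.nn import Module, ModuleList, Tensor

__all__ = [
    "ModelConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "AttentionGate",
    "EncoderBlock",
    "ThreefoldDecoderBlock",
    "CbamAgUNet",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
    "model_summary",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``bottleneck_filters`` must equal ``base_filters * 2**depth``; the two
    printed variants are 512 (base 32) and 256 (base 16) at depth 4.
    ``in_channels`` is 1 for the preprocessed single-channel pipeline, 3
    for raw RGB input.
    """

    in_channels: int = 1
    base_filters: int = 32
    depth: int = 4
    bottleneck_filters: int = 512
    reduction_ratio: int = 16
    use_cbam: bool = True
    use_ag: bool = True
    bottleneck_cbam: bool = True
    use_batchnorm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.reduction_ratio <= 0:
            raise ValueError("reduction_ratio must be positive")
        expected = self.base_filters * 2**self.depth
        if self.bottleneck_filters != expected:
            raise ValueError(
                f"bottleneck_filters must equal base_filters * 2**depth "
                f"= {expected}, got {self.bottleneck_filters}"
            )


class ChannelAttention(Module):
    """Per-channel gate from pooled descriptors through a shared MLP."""

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        avg = nn.reshape(nn.mean_axes(x, (2, 3)), (b, c))
        mx = nn.reshape(nn.max_axes(x, (2, 3)), (b, c))
        shared = lambda v: self.fc2(nn.relu(self.fc1(v)))
        mc = nn.sigmoid(shared(avg) + shared(mx))
        return nn.reshape(mc, (b, c, 1, 1))


class SpatialAttention(Module):
    """Per-location gate from channel-pooled maps through one 7x7 conv."""

    def __init__(self, rng: np.random.Generator, kernel_size: int = 7):
        self.conv = nn.Conv2d(2, 1, kernel_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = nn.mean_axes(x, (1,))
        mx = nn.max_axes(x, (1,))
        return nn.sigmoid(self.conv(nn.concat([avg, mx], axis=1)))


class CBAM(Module):
    """Sequential channel-first attention: F'' = M_s(M_c(F)*F) * (M_c(F)*F)."""

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator):
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(rng)

    def forward(self, x: Tensor) -> Tensor:
        f1 = self.channel(x) * x
        return self.spatial(f1) * f1


class AttentionGate(Module):
    """Skip-connection filter driven by the coarser gating signal."""

    def __init__(self, skip_channels: int, gating_channels: int,
                 inter_channels: int, rng: np.random.Generator):
        if inter_channels <= 0:
            raise ValueError("inter_channels must be positive")
        self.theta = nn.Conv2d(skip_channels, inter_channels, 1, rng)
        self.phi = nn.Conv2d(gating_channels, inter_channels, 1, rng)
        self.psi = nn.Conv2d(inter_channels, 1, 1, rng)

    def alpha(self, skip: Tensor, gating: Tensor) -> Tensor:
        g = self.phi(gating)
        if g.shape[2:] != skip.shape[2:]:
            g = nn.upsample_bilinear(g, (skip.shape[2], skip.shape[3]))
        return nn.sigmoid(self.psi(nn.relu(self.theta(skip) + g)))

    def forward(self, skip: Tensor, gating: Tensor) -> Tensor:
        return self.alpha(skip, gating) * skip


class BatchNorm2d(Module):
    """Per-channel normalisation; batch statistics while training, running
    averages at inference.  Off by default in this architecture."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = nn.Parameter(np.ones(channels, dtype=np.float32))
        self.beta = nn.Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mu, var = self.running_mean, self.running_var
        scale = Tensor((1.0 / np.sqrt(var + self.eps)).reshape(1, c, 1, 1)
                       .astype(np.float32))
        shift = Tensor((-mu).reshape(1, c, 1, 1).astype(np.float32))
        g = nn.reshape(self.gamma, (1, c, 1, 1))
        b = nn.reshape(self.beta, (1, c, 1, 1))
        return ((x + shift) * scale) * g + b


class _DoubleConv(Module):
    """Two 3x3 conv + ReLU layers (the structured convolutional block)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, use_batchnorm: bool = False):
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, rng)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, rng)
        self.bn1 = BatchNorm2d(out_channels) if use_batchnorm else None
        self.bn2 = BatchNorm2d(out_channels) if use_batchnorm else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        if self.bn1 is not None:
            h = self.bn1(h)
        h = nn.relu(h)
        h = self.conv2(h)
        if self.bn2 is not None:
            h = self.bn2(h)
        return nn.relu(h)


class EncoderBlock(Module):
    """Double conv (+CBAM) then 2x2 max-pool; returns the pre-pool features
    for the skip connection and the pooled tensor for the next stage."""

    def __init__(self, in_channels: int, filters: int, config: ModelConfig,
                 rng: np.random.Generator):
        self.block = _DoubleConv(in_channels, filters, rng,
                                 config.use_batchnorm)
        self.cbam = (CBAM(filters, config.reduction_ratio, rng)
                     if config.use_cbam else None)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        features = self.block(x)
        if self.cbam is not None:
            features = self.cbam(features)
        return features, nn.maxpool2d_2x(features)


class ThreefoldDecoderBlock(Module):
    """Attention-gate the skip, transposed-conv upsample the decoder
    signal, concatenate, double 3x3 conv, then CBAM."""

    def __init__(self, in_channels: int, skip_channels: int, filters: int,
                 config: ModelConfig, rng: np.random.Generator):
        inter = max(1, skip_channels // 2)
        self.gate = (AttentionGate(skip_channels, in_channels, inter, rng)
                     if config.use_ag else None)
        self.up = nn.ConvTranspose2d(in_channels, filters, rng)
        self.block = _DoubleConv(filters + skip_channels, filters, rng,
                                 config.use_batchnorm)
        self.cbam = (CBAM(filters, config.reduction_ratio, rng)
                     if config.use_cbam else None)

    def forward(self, decoder_in: Tensor, skip: Tensor) -> Tensor:
        if (decoder_in.shape[2] * 2, decoder_in.shape[3] * 2) != skip.shape[2:]:
            raise ValueError(
                f"decoder input {decoder_in.shape} must be half the spatial "
                f"size of the skip {skip.shape}"
            )
        attended = self.gate(skip, decoder_in) if self.gate is not None else skip
        up = self.up(decoder_in)
        out = self.block(nn.concat([up, attended], axis=1))
        if self.cbam is not None:
            out = self.cbam(out)
        return out


class CbamAgUNet(Module):
    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoders = ModuleList()
        in_ch = config.in_channels
        widths = [config.base_filters * 2**i for i in range(config.depth)]
        for f in widths:
            self.encoders.append(EncoderBlock(in_ch, f, config, rng))
            in_ch = f
        self.bottleneck = _DoubleConv(in_ch, config.bottleneck_filters, rng,
                                      config.use_batchnorm)
        self.bottleneck_attn = (
            CBAM(config.bottleneck_filters, config.reduction_ratio, rng)
            if config.use_cbam and config.bottleneck_cbam else None)
        self.decoders = ModuleList()
        dec_in = config.bottleneck_filters
        for f in reversed(widths):
            self.decoders.append(
                ThreefoldDecoderBlock(dec_in, f, f, config, rng))
            dec_in = f
        self.head = nn.Conv2d(dec_in, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        div = 2**self.config.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {div}"
            )
        skips = []
        h = x
        for enc in self.encoders:
            features, h = enc(h)
            skips.append(features)
        h = self.bottleneck(h)
        if self.bottleneck_attn is not None:
            h = self.bottleneck_attn(h)
        for dec, skip in zip(self.decoders, reversed(skips)):
            h = dec(h, skip)
        return nn.sigmoid(self.head(h))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass without building the autograd graph."""
        with nn.no_grad():
            return self.forward(Tensor(np.asarray(x, dtype=np.float32))).data


def build_model(config: ModelConfig | None = None, **overrides) -> CbamAgUNet:
    """Construct a seeded CBAM-AG-UNet from a config (or keyword overrides)."""
    if config is None:
        config = ModelConfig(**overrides)
    elif overrides:
        config = ModelConfig(**{**asdict(config), **overrides})
    return CbamAgUNet(config)


def save_checkpoint(model: CbamAgUNet, path: str | Path) -> None:
    """Write weights (npz) plus a JSON sidecar holding the ModelConfig."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2) + "\n")


def load_checkpoint(path: str | Path) -> CbamAgUNet:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing config sidecar {sidecar}")
    config = ModelConfig(**json.loads(sidecar.read_text()))
    model = CbamAgUNet(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def model_summary(config: ModelConfig | None = None) -> str:
    """Layer/parameter table for a config, plus the total count."""
    model = build_model(config or ModelConfig())
    lines = [f"{'parameter':60s} {'shape':>20s} {'count':>12s}"]
    total = 0
    for name, p in model.named_parameters():
        n = p.data.size
        total += n
        lines.append(f"{name:60s} {str(p.data.shape):>20s} {n:>12,d}")
    lines.append(f"{'total':60s} {'':>20s} {total:>12,d}")
    return "\n".join(lines)
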