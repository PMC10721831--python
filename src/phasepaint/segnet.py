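"""Segmentation-informed generator: attention encoder--decoder network.

Maps a grayscale phase tile to a per-pixel probability map for one
fluorescent channel.  The encoder stacks ResNeXt-style grouped-convolution
bottleneck blocks (three convolutions, three normalizations, two ReLUs per
stage, stride-2 at stage entry) with a squeeze-and-excitation (SE) channel
gate between the convolutional layers.  The decoder mirrors the encoder with
nearest upsampling, skip-connection concatenation, two conv/norm/ReLU pairs
and a concurrent spatial+channel squeeze-and-excitation (scSE) gate per
stage.  The prediction head fuses all decoder stages as a hypercolumn
(resized, concatenated), applies dropout, and emits a sigmoid probability per
input pixel.

One model is trained per fluorescent channel by default; a shared-trunk
multi-head variant is available via ``NetworkConfig.out_channels``.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, DimensionError
from .nn import Tensor


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    The defaults are a desk-scale preset (4 stages, 16 base channels) small
    enough to train on one CPU; :meth:`full_scale` returns a 5-stage preset
    with SE-ResNeXt50-style width (cardinality 32).
    """

    n_stages: int = 4
    base_channels: int = 16
    cardinality: int = 4
    se_reduction: int = 4
    dropout_p: float = 0.5
    in_channels: int = 1
    out_channels: int = 1
    norm: str = "batch"  # "batch" or "group"
    scse_combine: str = "max"  # "max" or "add"
    seed: int = 0

    def __post_init__(self):
        if self.n_stages < 2:
            raise ConfigurationError("n_stages must be >= 2")
        if self.base_channels < 4:
            raise ConfigurationError("base_channels must be >= 4")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError("dropout_p must be in [0, 1)")
        if self.base_channels % self.se_reduction:
            raise ConfigurationError("se_reduction must divide base_channels")
        if self.base_channels % self.cardinality:
            raise ConfigurationError("cardinality must divide base_channels")
        if self.norm not in ("batch", "group"):
            raise ConfigurationError(f"unknown norm {self.norm!r}")
        if self.scse_combine not in ("max", "add"):
            raise ConfigurationError(f"unknown scse_combine {self.scse_combine!r}")

    @classmethod
    def full_scale(cls, **overrides) -> "NetworkConfig":
        kw = dict(n_stages=5, base_channels=64, cardinality=32, se_reduction=16)
        kw.update(overrides)
        return cls(**kw)

    def stage_channels(self) -> list[int]:
        return [self.base_channels * 2**s for s in range(self.n_stages)]


def _make_norm(config: NetworkConfig, channels: int) -> nn.Module:
    if config.norm == "group":
        return nn.GroupNorm2d(channels, num_groups=min(8, channels))
    return nn.BatchNorm2d(channels)


class SEGate(nn.Module):
    """Channel squeeze-and-excitation.

    Global average pooling squeezes each channel to a scalar; two fully
    connected layers (bottleneck of ``channels / reduction``) with a sigmoid
    produce per-channel gates in (0, 1) that rescale the input.
    """

    def __init__(self, channels: int, reduction: int, rng=None):
        super().__init__()
        if channels % reduction:
            raise ConfigurationError(
                f"reduction {reduction} does not divide {channels} channels"
            )
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)

    def gates(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3))  # (N, C)
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.gates(x).reshape(n, c, 1, 1)


class SCSEGate(nn.Module):
    """Concurrent spatial and channel squeeze-and-excitation.

    The channel branch is :class:`SEGate`; the spatial branch pools along the
    channel axis and maps each location through a two-layer per-pixel MLP
    (1x1 convolutions) to a gate in (0, 1).  The two gated tensors are
    combined elementwise (maximum by default, addition optionally).
    """

    def __init__(self, channels: int, reduction: int, combine: str = "max", rng=None):
        super().__init__()
        self.combine = combine
        self.channel_gate = SEGate(channels, reduction, rng=rng)
        hidden = max(1, channels // reduction)
        self.sp1 = nn.Conv2d(1, hidden, 1, rng=rng)
        self.sp2 = nn.Conv2d(hidden, 1, 1, rng=rng)

    def spatial_gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=1, keepdims=True)  # (N, 1, H, W)
        return self.sp2(self.sp1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        cse = self.channel_gate(x)
        sse = x * self.spatial_gates(x)
        if self.combine == "add":
            return cse + sse
        return nn.maximum(cse, sse)


class ResNeXtBlock(nn.Module):
    """Grouped-convolution residual bottleneck with an SE gate.

    conv1x1 -> norm -> ReLU -> grouped conv3x3 (stride at stage entry) ->
    norm -> ReLU -> SE -> conv1x1 -> norm, plus a projection shortcut.
    """

    def __init__(self, config: NetworkConfig, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        groups = min(config.cardinality, out_ch)
        self.conv1 = nn.Conv2d(in_ch, out_ch, 1, bias=False, rng=rng)
        self.norm1 = _make_norm(config, out_ch)
        self.conv2 = nn.Conv2d(
            out_ch, out_ch, 3, stride=stride, padding=1, groups=groups, bias=False, rng=rng
        )
        self.norm2 = _make_norm(config, out_ch)
        self.se = SEGate(out_ch, config.se_reduction, rng=rng)
        self.conv3 = nn.Conv2d(out_ch, out_ch, 1, bias=False, rng=rng)
        self.norm3 = _make_norm(config, out_ch)
        self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
        self.proj_norm = _make_norm(config, out_ch)

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y)).relu()
        y = self.se(y)
        y = self.norm3(self.conv3(y))
        return y + self.proj_norm(self.proj(x))


class DecoderBlock(nn.Module):
    """Upsample, concatenate skip features, refine, and gate with scSE."""

    def __init__(self, config: NetworkConfig, in_ch: int, skip_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch + skip_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.norm1 = _make_norm(config, out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.norm2 = _make_norm(config, out_ch)
        self.scse = SCSEGate(out_ch, config.se_reduction, config.scse_combine, rng=rng)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = nn.upsample_nearest(x, 2)
        if skip is not None:
            x = nn.concat([x, skip], axis=1)
        x = self.norm1(self.conv1(x)).relu()
        x = self.norm2(self.conv2(x)).relu()
        return self.scse(x)


class SegNet(nn.Module):
    """The full phase-to-probability generator."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        chs = config.stage_channels()

        stages = []
        in_ch = config.in_channels
        for ch in chs:
            stages.append(ResNeXtBlock(config, in_ch, ch, stride=2, rng=rng))
            in_ch = ch
        self.stages = nn.ModuleList(stages)

        # decoder: deepest stage is upsampled and fused with progressively
        # shallower encoder features; the last block has no skip.
        decoders = []
        dec_in = chs[-1]
        for k in range(config.n_stages - 2, -2, -1):
            skip_ch = chs[k] if k >= 0 else 0
            out_ch = chs[k] if k >= 0 else config.base_channels
            decoders.append(DecoderBlock(config, dec_in, skip_ch, out_ch, rng=rng))
            dec_in = out_ch
        self.decoders = nn.ModuleList(decoders)

        hyper_ch = sum(chs[:-1]) + config.base_channels
        self.dropout = nn.Dropout(config.dropout_p, seed=config.seed + 1)
        self.head = nn.Conv2d(hyper_ch, config.out_channels, 1, rng=rng)

    # -- stages ------------------------------------------------------------

    def encode(self, x: Tensor | np.ndarray) -> list[Tensor]:
        """Run the encoder; stage s output has spatial size input / 2^(s+1)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=nn.DEFAULT_DTYPE))
        h, w = x.shape[2], x.shape[3]
        f = 2**self.config.n_stages
        if h % f or w % f:
            raise DimensionError(
                f"input {h}x{w} not divisible by 2^{self.config.n_stages}"
            )
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats

    def decode(self, pyramid: list[Tensor]) -> Tensor:
        """Run the decoder and hypercolumn head; returns sigmoid probabilities."""
        if len(pyramid) != self.config.n_stages:
            raise DimensionError(
                f"pyramid has {len(pyramid)} stages, config expects "
                f"{self.config.n_stages}"
            )
        x = pyramid[-1]
        skips = list(pyramid[:-1])[::-1] + [None]
        dec_outputs = []
        for block, skip in zip(self.decoders, skips):
            x = block(x, skip)
            dec_outputs.append(x)
        # hypercolumn fusion: every decoder output resized to full resolution
        full = dec_outputs[-1].shape[2]
        resized = [
            out if out.shape[2] == full else nn.upsample_nearest(out, full // out.shape[2])
            for out in dec_outputs
        ]
        fused = nn.concat(resized, axis=1)
        fused = self.dropout(fused)
        return self.head(fused).sigmoid()

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        return self.decode(self.encode(x))

    def predict(self, tiles: np.ndarray) -> np.ndarray:
        """Eval-mode probabilities for a (N, H, W) or (N, 1, H, W) batch."""
        arr = np.asarray(tiles, dtype=nn.DEFAULT_DTYPE)
        if arr.ndim == 3:
            arr = arr[:, None]
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(arr).data
        finally:
            self.train(was_training)
        return out[:, 0] if self.config.out_channels == 1 else out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: SegNet, extra: dict | None = None) -> None:
    """Serialize weights plus the embedded NetworkConfig to one .npz file."""
    meta = {"config": asdict(model.config), "extra": extra or {}}
    arrays = {"__meta__": np.array(json.dumps(meta))}
    arrays.update(model.state_dict())
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[SegNet, dict]:
    """Rebuild a model (and any extra metadata) from a checkpoint file."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = NetworkConfig(**meta["config"])
    model = SegNet(config)
    model.load_state_dict(state)
    model.eval()
    return model, meta.get("extra", {})
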