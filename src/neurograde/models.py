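"""The three 18-layer residual classifiers for single-channel 3D volumes.

All three share the same skeleton: a stem, four stages of two basic residual
blocks with widths doubling from ``base_width`` (64, 128, 256, 512 at the
default width), global adaptive average pooling to a 512-feature vector,
dropout, and a linear head with one output per class.  They differ only in
the convolution mode of the stem and stages:

* ``RESNET3D`` -- full (3,3,3) convolutions in every stage.
* ``RESNET_2P1D`` -- every 3D convolution factorized into an in-plane (1,3,3)
  convolution and a slice-axis (3,1,1) convolution with batch-norm and ReLU
  in between; the factorization width is chosen by :func:`midplanes_2p1d` so
  the parameter budget matches the unfactorized convolution.
* ``RESNET_MIXED`` -- full 3D convolutions in stage 1, in-plane (1,3,3)
  convolutions in stages 2-4.

The slice axis is the first axis of every kernel tuple; it plays the role of
the temporal axis of the video architectures these models derive from.
Convolutions are bias-free, batch-norms affine, and the head carries a bias
-- the combination under which the parameter totals of the full-width
variants are exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np

from . import nn
from .nn import ShapeError

__all__ = [
    "ArchitectureKind",
    "Network",
    "NetworkConfig",
    "architecture_summary",
    "build_network",
    "classify",
    "count_trainable_parameters",
    "load_checkpoint",
    "load_pretrained",
    "midplanes_2p1d",
    "save_checkpoint",
    "state_dict",
]


class ArchitectureKind(str, Enum):
    RESNET3D = "resnet3d"
    RESNET_2P1D = "resnet2p1d"
    RESNET_MIXED = "resnet_mixed"


_STAGE_MODES: dict[ArchitectureKind, tuple[str, str, str, str]] = {
    ArchitectureKind.RESNET3D: ("3d", "3d", "3d", "3d"),
    ArchitectureKind.RESNET_2P1D: ("2p1d", "2p1d", "2p1d", "2p1d"),
    ArchitectureKind.RESNET_MIXED: ("3d", "2d", "2d", "2d"),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Which architecture to build and at what width.

    ``base_width`` scales every stage in lockstep (stage widths are
    ``base_width * (1, 2, 4, 8)``); 64 is the full published width, smaller
    values give the width-reduced variants used for CPU-scale experiments.
    """

    kind: ArchitectureKind
    in_channels: int = 1
    n_classes: int = 3
    dropout_p: float = 0.3
    stem_midplanes: int = 45
    base_width: int = 64
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)
    bn_track_running_stats: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "kind", ArchitectureKind(self.kind))
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.base_width < 1 or self.stem_midplanes < 1:
            raise ValueError("widths must be positive")
        if len(self.blocks_per_stage) != 4 or any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("blocks_per_stage must be four positive integers")

    @property
    def stage_widths(self) -> tuple[int, int, int, int]:
        w = self.base_width
        return (w, 2 * w, 4 * w, 8 * w)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kind"] = self.kind.value
        d["blocks_per_stage"] = list(self.blocks_per_stage)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkConfig":
        d = dict(d)
        d["blocks_per_stage"] = tuple(d.get("blocks_per_stage", (2, 2, 2, 2)))
        return cls(**d)


def midplanes_2p1d(n_in: int, n_out: int, t: int = 3, d: int = 3) -> int:
    """Internal width of a (2+1)D factorized convolution.

    Chosen so that the 2D (d x d) plus 1D (t) pair has approximately the same
    number of weights as the full t x d x d convolution it replaces:
    ``floor(t*d^2*n_in*n_out / (d^2*n_in + t*n_out))``.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("channel counts must be >= 1")
    return (t * d * d * n_in * n_out) // (d * d * n_in + t * n_out)


class _StemConv(nn.Module):
    """Stem for the full-3D and mixed models: (3,7,7) conv, BN, ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype):
        super().__init__()
        self.conv1 = self.add_child(
            "conv1", nn.Conv3d(in_ch, out_ch, (3, 7, 7), (1, 2, 2), (1, 3, 3), rng=rng, dtype=dtype)
        )
        self.bn1 = self.add_child("bn1", nn.BatchNorm3d(out_ch, dtype=dtype))
        self.relu1 = nn.ReLU()

    def forward(self, x, training=False):
        return self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)

    def backward(self, dy):
        # the stem is the first layer: no input gradient is needed
        self.conv1.backward(self.bn1.backward(self.relu1.backward(dy)), need_dx=False)
        return None


class _Stem2Plus1(nn.Module):
    """Factorized stem: in-plane 7x7 conv to ``mid`` channels, then a
    slice-axis kernel-3 conv to the stage width, BN+ReLU after each."""

    def __init__(self, in_ch: int, mid: int, out_ch: int, rng, dtype):
        super().__init__()
        self.conv1 = self.add_child(
            "conv1", nn.Conv3d(in_ch, mid, (1, 7, 7), (1, 2, 2), (0, 3, 3), rng=rng, dtype=dtype)
        )
        self.bn1 = self.add_child("bn1", nn.BatchNorm3d(mid, dtype=dtype))
        self.conv2 = self.add_child(
            "conv2", nn.Conv3d(mid, out_ch, (3, 1, 1), (1, 1, 1), (1, 0, 0), rng=rng, dtype=dtype)
        )
        self.bn2 = self.add_child("bn2", nn.BatchNorm3d(out_ch, dtype=dtype))
        self.relu1 = nn.ReLU()
        self.relu2 = nn.ReLU()

    def forward(self, x, training=False):
        x = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        return self.relu2.forward(self.bn2.forward(self.conv2.forward(x, training), training), training)

    def backward(self, dy):
        dy = self.conv2.backward(self.bn2.backward(self.relu2.backward(dy)))
        self.conv1.backward(self.bn1.backward(self.relu1.backward(dy)), need_dx=False)
        return None


class _Conv2Plus1(nn.Module):
    """One factorized conv: in-plane 2D conv -> BN -> ReLU -> slice 1D conv."""

    def __init__(self, in_ch: int, out_ch: int, mid: int, stride: int, rng, dtype):
        super().__init__()
        s = stride
        self.spatial = self.add_child(
            "spatial", nn.Conv3d(in_ch, mid, (1, 3, 3), (1, s, s), (0, 1, 1), rng=rng, dtype=dtype)
        )
        self.bn = self.add_child("bn", nn.BatchNorm3d(mid, dtype=dtype))
        self.temporal = self.add_child(
            "temporal", nn.Conv3d(mid, out_ch, (3, 1, 1), (s, 1, 1), (1, 0, 0), rng=rng, dtype=dtype)
        )
        self.relu = nn.ReLU()

    def forward(self, x, training=False):
        x = self.relu.forward(self.bn.forward(self.spatial.forward(x, training), training), training)
        return self.temporal.forward(x, training)

    def backward(self, dy):
        dy = self.temporal.backward(dy)
        return self.spatial.backward(self.bn.backward(self.relu.backward(dy)))


class _Downsample(nn.Module):
    """Identity-path projection: kernel-1 strided conv followed by BN."""

    def __init__(self, in_ch: int, out_ch: int, stride: tuple[int, int, int], rng, dtype):
        super().__init__()
        self.conv = self.add_child(
            "conv", nn.Conv3d(in_ch, out_ch, (1, 1, 1), stride, (0, 0, 0), rng=rng, dtype=dtype)
        )
        self.bn = self.add_child("bn", nn.BatchNorm3d(out_ch, dtype=dtype))

    def forward(self, x, training=False):
        return self.bn.forward(self.conv.forward(x, training), training)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(dy))


class _BasicBlock(nn.Module):
    """conv -> BN -> ReLU -> conv -> BN, add the (possibly projected)
    identity, final ReLU.  ``mode`` selects full-3D, in-plane 2D, or (2+1)D
    convolutions; the stride of the first conv carries the stage's spatial
    downsampling."""

    def __init__(self, mode: str, in_ch: int, out_ch: int, stride: int, rng, dtype):
        super().__init__()
        self.mode = mode
        s = stride
        if mode == "3d":
            self.conv1 = self.add_child(
                "conv1", nn.Conv3d(in_ch, out_ch, (3, 3, 3), (s, s, s), (1, 1, 1), rng=rng, dtype=dtype)
            )
            self.conv2 = self.add_child(
                "conv2", nn.Conv3d(out_ch, out_ch, (3, 3, 3), (1, 1, 1), (1, 1, 1), rng=rng, dtype=dtype)
            )
            ds_stride = (s, s, s)
        elif mode == "2d":
            self.conv1 = self.add_child(
                "conv1", nn.Conv3d(in_ch, out_ch, (1, 3, 3), (1, s, s), (0, 1, 1), rng=rng, dtype=dtype)
            )
            self.conv2 = self.add_child(
                "conv2", nn.Conv3d(out_ch, out_ch, (1, 3, 3), (1, 1, 1), (0, 1, 1), rng=rng, dtype=dtype)
            )
            ds_stride = (1, s, s)
        elif mode == "2p1d":
            mid = midplanes_2p1d(in_ch, out_ch)
            self.conv1 = self.add_child("conv1", _Conv2Plus1(in_ch, out_ch, mid, s, rng, dtype))
            self.conv2 = self.add_child("conv2", _Conv2Plus1(out_ch, out_ch, mid, 1, rng, dtype))
            ds_stride = (s, s, s)
        else:  # pragma: no cover - guarded by the builder
            raise ValueError(f"unknown conv mode {mode!r}")
        self.bn1 = self.add_child("bn1", nn.BatchNorm3d(out_ch, dtype=dtype))
        self.bn2 = self.add_child("bn2", nn.BatchNorm3d(out_ch, dtype=dtype))
        self.relu1 = nn.ReLU()
        self.relu_out = nn.ReLU()
        self.downsample = None
        if s != 1 or in_ch != out_ch:
            self.downsample = self.add_child("downsample", _Downsample(in_ch, out_ch, ds_stride, rng, dtype))

    def forward(self, x, training=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        idn = self.downsample.forward(x, training) if self.downsample is not None else x
        return self.relu_out.forward(h + idn, training)

    def backward(self, dy):
        dz = self.relu_out.backward(dy)
        dh = self.bn2.backward(dz)
        dh = self.conv2.backward(dh)
        dh = self.bn1.backward(self.relu1.backward(dh))
        dx = self.conv1.backward(dh)
        if self.downsample is not None:
            dx = dx + self.downsample.backward(dz)
        else:
            dx = dx + dz
        return dx


class _Stage(nn.Module):
    def __init__(self, mode: str, in_ch: int, out_ch: int, n_blocks: int, stride: int, rng, dtype):
        super().__init__()
        self.conv_mode = mode
        self.blocks: list[_BasicBlock] = []
        for i in range(n_blocks):
            blk = _BasicBlock(mode, in_ch if i == 0 else out_ch, out_ch,
                              stride if i == 0 else 1, rng, dtype)
            self.blocks.append(self.add_child(f"block{i + 1}", blk))

    def forward(self, x, training=False):
        for blk in self.blocks:
            x = blk.forward(x, training)
        return x

    def backward(self, dy):
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        return dy


class Network(nn.Module):
    """A built classifier; use :func:`build_network` to construct one."""

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        super().__init__()
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        init_seed, drop_seed = ss.spawn(2)
        rng = np.random.default_rng(init_seed)
        widths = config.stage_widths
        kind = config.kind
        if kind is ArchitectureKind.RESNET_2P1D:
            stem = _Stem2Plus1(config.in_channels, config.stem_midplanes, widths[0], rng, dtype)
        else:
            stem = _StemConv(config.in_channels, widths[0], rng, dtype)
        self.stem = self.add_child("stem", stem)
        self.stages: list[_Stage] = []
        in_ch = widths[0]
        for i, (mode, width, n_blocks) in enumerate(
            zip(_STAGE_MODES[kind], widths, config.blocks_per_stage), start=1
        ):
            stage = _Stage(mode, in_ch, width, n_blocks, 1 if i == 1 else 2, rng, dtype)
            self.stages.append(self.add_child(f"layer{i}", stage))
            in_ch = width
        self.pool = nn.AdaptiveAvgPool3d()
        self.dropout = nn.Dropout(config.dropout_p, rng=np.random.default_rng(drop_seed))
        self.fc = self.add_child("fc", nn.Linear(widths[-1], config.n_classes, rng=rng, dtype=dtype))
        for _, mod in self.named_modules():
            if isinstance(mod, nn.BatchNorm3d):
                mod.track_running_stats = config.bn_track_running_stats

    @property
    def stage_conv_modes(self) -> list[str]:
        return [s.conv_mode for s in self.stages]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError(f"expected (channel, slice, row, col) input, got shape {x.shape}")
        try:
            x = self.stem.forward(x, training)
        except ShapeError as e:
            raise ShapeError(f"stem: {e}") from None
        for i, stage in enumerate(self.stages, start=1):
            try:
                x = stage.forward(x, training)
            except ShapeError as e:
                raise ShapeError(f"layer{i}: {e}") from None
        v = self.pool.forward(x, training)
        v = self.dropout.forward(v, training)
        return self.fc.forward(v, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.fc.backward(dlogits)
        dy = self.dropout.backward(dy)
        dy = self.pool.backward(dy)
        for stage in reversed(self.stages):
            dy = stage.backward(dy)
        self.stem.backward(dy)


def build_network(cfg: NetworkConfig) -> Network:
    """Construct one of the three architectures from its configuration."""
    return Network(cfg)


def count_trainable_parameters(net: Network) -> int:
    """Exact number of learnable scalars (conv weights, BN scale/shift, head)."""
    return sum(p.size for _, p in net.named_parameters())


def architecture_summary(net_or_cfg) -> dict:
    """Full layer table plus stage conv modes, for auditing parameter counts.

    Each row carries the structural fields (type, channels, kernel, stride,
    padding) and the layer's parameter count, so the total can be recomputed
    independently from the structure.
    """
    net = net_or_cfg if isinstance(net_or_cfg, Network) else build_network(net_or_cfg)
    rows = []
    for name, mod in net.named_modules():
        if isinstance(mod, nn.Conv3d):
            rows.append({
                "name": name, "type": "conv3d",
                "in_channels": mod.in_channels, "out_channels": mod.out_channels,
                "kernel": list(mod.kernel), "stride": list(mod.stride),
                "padding": list(mod.padding), "parameters": mod.weight.size,
            })
        elif isinstance(mod, nn.BatchNorm3d):
            rows.append({
                "name": name, "type": "batchnorm3d",
                "in_channels": mod.channels, "out_channels": mod.channels,
                "kernel": None, "stride": None, "padding": None,
                "parameters": mod.gamma.size + mod.beta.size,
            })
        elif isinstance(mod, nn.Linear):
            rows.append({
                "name": name, "type": "linear",
                "in_channels": mod.in_features, "out_channels": mod.out_features,
                "kernel": None, "stride": None, "padding": None,
                "parameters": mod.weight.size + mod.bias.size,
            })
    return {
        "kind": net.config.kind.value,
        "stage_conv_modes": net.stage_conv_modes,
        "layers": rows,
        "total_parameters": count_trainable_parameters(net),
    }


def classify(net: Network, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode logits for a (batch, channel, slice, row, col) array."""
    batch = np.asarray(batch)
    if batch.ndim != 5:
        raise ValueError(f"expected a 5D batch, got shape {batch.shape}")
    return np.stack([net.forward(sample, training=False) for sample in batch])


def state_dict(net: Network) -> dict[str, np.ndarray]:
    return {name: p.value.copy() for name, p in net.named_parameters()}


def load_pretrained(net: Network, source: Mapping[str, np.ndarray]) -> Network:
    """Copy every non-stem, non-head parameter from ``source`` into ``net``.

    This is the weight-transfer policy for donors trained on a task with a
    different input-channel count and class count: the stem and the final
    fully connected layer keep their fresh random initialization.
    """
    for name, p in net.named_parameters():
        if name.startswith(("stem.", "fc.")):
            continue
        if name not in source:
            raise KeyError(f"source is missing transferable parameter '{name}'")
        src = np.asarray(source[name])
        if src.shape != p.value.shape:
            raise ValueError(
                f"shape mismatch for parameter '{name}': "
                f"network {p.value.shape} vs source {src.shape}"
            )
        p.value[...] = src.astype(p.value.dtype)
    return net


def save_checkpoint(net: Network, path) -> None:
    arrays = {f"param:{n}": p.value for n, p in net.named_parameters()}
    arrays.update({f"buffer:{n}": b for n, b in net.named_buffers()})
    np.savez(path, __config__=np.frombuffer(
        json.dumps(net.config.to_dict()).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Network:
    with np.load(Path(path)) as data:
        cfg = NetworkConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        net = build_network(cfg)
        params = dict(net.named_parameters())
        buffers = dict(net.named_buffers())
        for key in data.files:
            if key.startswith("param:"):
                params[key[6:]].value[...] = data[key]
            elif key.startswith("buffer:"):
                buffers[key[7:]][...] = data[key]
    return net
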