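"""Attention-based multi-scale counting network.

The model has two parts:

* **FEN** (feature extraction network): the convolutional prefix of VGG-16.
  The default keeps the first 10 conv layers with the 3 interior max-pools,
  so features come out at 512 channels and 1/8 of the input resolution;
  7- and 13-layer variants (2 and 5 pools, 1/4 and 1/32 resolution) are
  available for ablations.
* **AMRN** (attention-based multi-scale regression network): three parallel
  conv branches with kernel sizes 3x3, 5x5 and 7x7 (receptive fields tuned
  to different mosquito scales), each three convs deep with successively
  decreasing channel counts and ReLU after every conv.  A squeeze-and-
  excitation (SE) channel-attention block gates the 7x7 branch.  Branch
  outputs are concatenated and mapped to a single-channel density map by a
  1x1 convolution (followed by a ReLU so predicted density is non-negative).

The predicted count of an image is the sum of its predicted density map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .density import DensityMap
from .nn import Conv2d, GlobalAvgPool, Layer, Linear, MaxPool2x2, Param, ReLU, \
    Sequential, Sigmoid

__all__ = [
    "ModelConfig",
    "SEModule",
    "build_fen",
    "build_amrn",
    "MosquitoCounter",
    "fen_output_shape",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

#: VGG-16 conv widths in order; max-pools sit after convs 2, 4, 7, 10, 13.
_VGG16_WIDTHS = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512)

#: depth -> (number of convs, pool positions kept).  The 10-layer front end
#: keeps only the first three pools (1/8 resolution); 13 layers keep all
#: five (1/32); 7 layers keep two (1/4).
_FEN_SPECS: dict[int, tuple[int, tuple[int, ...]]] = {
    7: (7, (2, 4)),
    10: (10, (2, 4, 7)),
    13: (13, (2, 4, 7, 10, 13)),
}

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class ModelConfig:
    """Architectural description of the counting network.

    ``fen_channels`` overrides the per-conv widths of the front end (None =
    standard VGG-16 widths); reduced widths give a desk-scale model that
    trains from random init in minutes while keeping the architecture.
    """

    fen_layers: int = 10
    fen_channels: Sequence[int] | None = None
    branch_kernels: Sequence[int] = (3, 5, 7)
    branch_channels: Sequence[int] = (256, 128, 64)
    se_branches: frozenset[int] = frozenset({7})
    se_reduction: int = 16
    final_relu: bool = True

    def __post_init__(self) -> None:
        if self.fen_layers not in _FEN_SPECS:
            raise ValueError(
                f"fen_layers must be one of {sorted(_FEN_SPECS)}, got {self.fen_layers}")
        n_convs = _FEN_SPECS[self.fen_layers][0]
        if self.fen_channels is not None:
            self.fen_channels = tuple(int(c) for c in self.fen_channels)
            if len(self.fen_channels) != n_convs:
                raise ValueError(
                    f"fen_channels needs {n_convs} entries for a "
                    f"{self.fen_layers}-layer front end, got {len(self.fen_channels)}")
        self.branch_kernels = tuple(int(k) for k in self.branch_kernels)
        if not self.branch_kernels:
            raise ValueError("at least one branch kernel required")
        if any(k % 2 == 0 or k < 1 for k in self.branch_kernels):
            raise ValueError(f"branch kernels must be odd, got {self.branch_kernels}")
        self.branch_channels = tuple(int(c) for c in self.branch_channels)
        if len(self.branch_channels) != 3:
            raise ValueError("each branch has exactly 3 conv layers")
        if not all(a > b for a, b in zip(self.branch_channels,
                                         self.branch_channels[1:])):
            raise ValueError(
                f"branch channels must strictly decrease, got {self.branch_channels}")
        self.se_branches = frozenset(int(k) for k in self.se_branches)
        if not self.se_branches <= set(self.branch_kernels):
            raise ValueError(
                f"se_branches {sorted(self.se_branches)} not a subset of "
                f"branch kernels {self.branch_kernels}")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be positive")

    @property
    def fen_scale(self) -> int:
        """Total spatial downsampling factor of the front end."""
        return 2 ** len(_FEN_SPECS[self.fen_layers][1])

    @property
    def fen_widths(self) -> tuple[int, ...]:
        n_convs = _FEN_SPECS[self.fen_layers][0]
        return tuple(self.fen_channels) if self.fen_channels is not None \
            else _VGG16_WIDTHS[:n_convs]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["se_branches"] = sorted(self.se_branches)
        d["fen_channels"] = list(self.fen_channels) if self.fen_channels else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "se_branches" in d:
            d["se_branches"] = frozenset(d["se_branches"])
        return cls(**d)


def fen_output_shape(input_hw: tuple[int, int], fen_layers: int = 10
                     ) -> tuple[int, int]:
    """Spatial output dims: successive floor-halvings, one per max-pool."""
    h, w = input_hw
    for _ in _FEN_SPECS[fen_layers][1]:
        h, w = h // 2, w // 2
    return h, w


class SEModule(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: per-channel global average pool, H x W x C -> C.
    Excitation: two-layer bottleneck C -> C/r -> C with ReLU then sigmoid,
    producing gates in (0, 1) per channel.  Output is the input rescaled
    channel-wise by its gate, so gated magnitudes never exceed the input.
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator, name: str = "se"):
        if reduction < 1:
            raise ValueError("reduction must be positive")
        hidden = max(channels // reduction, 4)
        self.channels = channels
        self.squeeze = GlobalAvgPool()
        self.fc1 = Linear(channels, hidden, rng, name=f"{name}.fc1")
        self.relu = ReLU()
        self.fc2 = Linear(hidden, channels, rng, name=f"{name}.fc2")
        self.sigmoid = Sigmoid()

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def gates(self, x: np.ndarray) -> np.ndarray:
        """The excitation weights z-hat in (0,1)^C for a batch (no caching)."""
        z = x.mean(axis=(2, 3))
        a = z @ self.fc1.weight.value.T + self.fc1.bias.value
        a = np.maximum(a, 0.0)
        a = a @ self.fc2.weight.value.T + self.fc2.bias.value
        return 1.0 / (1.0 + np.exp(-a))

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = self.squeeze.forward(x)
        s = self.sigmoid.forward(self.fc2.forward(self.relu.forward(
            self.fc1.forward(z))))
        self._x, self._s = x, s
        return x * s[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ds = (grad * self._x).sum(axis=(2, 3))
        dx = grad * self._s[:, :, None, None]
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(
            self.sigmoid.backward(ds))))
        return dx + self.squeeze.backward(dz)


def build_fen(config: ModelConfig, pretrained: bool = False,
              weights: str | Path | None = None, seed: int = 0,
              init: str = "he") -> Sequential:
    """Truncated-VGG feature extractor per the config.

    With ``pretrained`` a ``.npz`` of conv weights must be supplied (keys
    ``fen.conv{i}.weight`` of shape (out, in*k*k) and ``fen.conv{i}.bias``);
    otherwise weights are seeded random.
    """
    rng = np.random.default_rng(seed)
    widths = config.fen_widths
    _, pools = _FEN_SPECS[config.fen_layers]
    layers: list[Layer] = []
    in_ch = 3
    for i, out_ch in enumerate(widths, start=1):
        layers.append(Conv2d(in_ch, out_ch, 3, rng, init=init, name=f"fen.conv{i}"))
        layers.append(ReLU())
        if i in pools:
            layers.append(MaxPool2x2())
        in_ch = out_ch
    fen = Sequential(layers)
    if pretrained:
        if weights is None:
            raise ValueError(
                "pretrained=True needs a weights file (.npz of VGG-16 conv "
                "weights); none bundled with the package")
        _load_params(fen.params(), np.load(weights))
    return fen


class _Branch(Layer):
    """One AMRN branch: three same-padding convs (ReLU after each), with an
    optional SE block gating the branch's final representation."""

    def __init__(self, kernel: int, in_ch: int, channels: Sequence[int],
                 with_se: bool, se_reduction: int,
                 rng: np.random.Generator, init: str, name: str):
        layers: list[Layer] = []
        prev = in_ch
        for j, ch in enumerate(channels, start=1):
            layers.append(Conv2d(prev, ch, kernel, rng, init=init,
                                 name=f"{name}.conv{j}"))
            layers.append(ReLU())
            prev = ch
        if with_se:
            layers.append(SEModule(prev, se_reduction, rng, name=f"{name}.se"))
        self.net = Sequential(layers)
        self.out_channels = prev
        self.kernel = kernel
        self.has_se = with_se

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


class MultiScaleHead(Layer):
    """The AMRN: parallel branches -> channel concat -> 1x1 conv -> density."""

    def __init__(self, config: ModelConfig, in_channels: int, seed: int = 0,
                 init: str = "he"):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.branches = [
            _Branch(k, in_channels, config.branch_channels,
                    with_se=(k in config.se_branches),
                    se_reduction=config.se_reduction,
                    rng=rng, init=init, name=f"amrn.b{k}")
            for k in config.branch_kernels
        ]
        concat_ch = sum(b.out_channels for b in self.branches)
        # narrow weights + small positive bias keep the final ReLU alive at
        # init for any seed (a wide-init 1x1 over all-positive activations
        # can start uniformly negative, freezing the output at zero)
        self.fuse = Conv2d(concat_ch, 1, 1, rng, init="narrow", name="amrn.fuse")
        self.fuse.bias.value[:] = 0.01
        self.final_relu = ReLU() if config.final_relu else None

    def params(self) -> list[Param]:
        ps = [p for b in self.branches for p in b.params()]
        return ps + self.fuse.params()

    def forward(self, x: np.ndarray, raw: bool = False) -> np.ndarray:
        """``raw`` skips the final ReLU (used when optimizing the density
        loss, which sees the unclamped map; see backward)."""
        outs = [b.forward(x) for b in self.branches]
        cat = np.concatenate(outs, axis=1)
        y = self.fuse.forward(cat)
        self._raw = raw
        if self.final_relu is not None and not raw:
            y = self.final_relu.forward(y)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.final_relu is not None and not self._raw:
            grad = self.final_relu.backward(grad)
        dcat = self.fuse.backward(grad)
        dx = None
        c0 = 0
        for b in self.branches:
            c1 = c0 + b.out_channels
            dxi = b.backward(dcat[:, c0:c1])
            dx = dxi if dx is None else dx + dxi
            c0 = c1
        return dx


def build_amrn(config: ModelConfig, in_channels: int | None = None,
               seed: int = 0, init: str = "he") -> MultiScaleHead:
    """The multi-scale regression head mapping FEN features to density."""
    if in_channels is None:
        in_channels = config.fen_widths[-1]
    return MultiScaleHead(config, in_channels, seed=seed, init=init)


class MosquitoCounter:
    """End-to-end counting network: image in, density map at 1/``scale``
    resolution out.  Accepts any input size >= 4x the downsampling factor."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 init: str = "he", pretrained: bool = False,
                 fen_weights: str | Path | None = None):
        self.config = config if config is not None else ModelConfig()
        self.pretrained = pretrained
        self.fen = build_fen(self.config, pretrained=pretrained,
                             weights=fen_weights, seed=seed, init=init)
        self.head = build_amrn(self.config, self.config.fen_widths[-1],
                               seed=seed, init=init)
        self.scale = self.config.fen_scale

    # --- parameters ------------------------------------------------------
    def params(self) -> list[Param]:
        return self.fen.params() + self.head.params()

    # --- forward / backward ---------------------------------------------
    @property
    def min_input(self) -> int:
        return 4 * self.scale

    def forward_tensor(self, x: np.ndarray, raw: bool = False) -> np.ndarray:
        """NCHW float batch -> N x 1 x H' x W' density batch.

        With ``raw`` the final ReLU clamp is skipped: training optimizes the
        unclamped map, because a ReLU trained through can die irrecoverably
        (one momentum overshoot that pushes the whole map negative zeroes
        every gradient thereafter).  Prediction always clamps.
        """
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected Nx3xHxW input, got shape {x.shape}")
        if x.shape[2] < self.min_input or x.shape[3] < self.min_input:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} below the {self.min_input}px "
                f"minimum for a 1/{self.scale} model")
        return self.head.forward(self.fen.forward(x), raw=raw)

    def backward_tensor(self, grad: np.ndarray) -> np.ndarray:
        return self.fen.backward(self.head.backward(grad))

    # --- image interface -------------------------------------------------
    def preprocess(self, image: np.ndarray) -> np.ndarray:
        """HxWx3 uint8 -> 1x3xHxW float; ImageNet-normalized when running
        with pretrained features, plain [0,1] scaling otherwise."""
        x = np.asarray(image, dtype=np.float64) / 255.0
        if self.pretrained:
            x = (x - IMAGENET_MEAN) / IMAGENET_STD
        return x.transpose(2, 0, 1)[None]

    def predict_density(self, image: np.ndarray) -> DensityMap:
        """Predicted density map for one HxWx3 image."""
        y = self.forward_tensor(self.preprocess(image))
        return DensityMap(y[0, 0], scale=self.scale)

    def predict_count(self, image: np.ndarray) -> float:
        return self.predict_density(image).mass

    # --- checkpointing ---------------------------------------------------
    def save_weights(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, **{p.name: p.value for p in self.params()})
        path.with_suffix(".json").write_text(
            json.dumps(self.config.to_dict(), indent=1))
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    def load_weights(self, path: str | Path) -> None:
        _load_params(self.params(), np.load(path))

    @classmethod
    def from_checkpoint(cls, path: str | Path, **kwargs) -> "MosquitoCounter":
        path = Path(path)
        cfg_path = path.with_suffix(".json")
        config = ModelConfig.from_dict(json.loads(cfg_path.read_text())) \
            if cfg_path.exists() else None
        model = cls(config=config, **kwargs)
        model.load_weights(path)
        return model


def _load_params(params: Sequence[Param], archive) -> None:
    for p in params:
        if p.name not in archive:
            raise KeyError(f"weights file missing parameter {p.name!r}")
        value = np.asarray(archive[p.name], dtype=np.float64)
        if value.shape != p.value.shape:
            raise ValueError(
                f"{p.name}: shape {value.shape} != expected {p.value.shape}")
        p.value = value
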