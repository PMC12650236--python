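"""The four 2D encoder-decoder variants and their training loop.

All variants share the same symmetric layout: ``depth`` down-samplings and
``depth`` up-samplings (depth+1 resolution scales), feature channels
doubling per level (64, 128, 256, 512, 1024 at the defaults), 2x2
transpose-convolution upsampling, and skip connections. Blocks are two
biased 3x3 convolutions with ReLU and no normalization layers; the output
head is a biased 1x1 convolution. On top of this shared skeleton:

* ``unet``            — plain double-conv blocks with concatenated skips;
* ``resunet``         — residual double-conv blocks (1x1 projection
                        shortcut whenever the channel count changes);
* ``attention_unet``  — additive attention gates on each skip, with inner
                        channels = skip channels / 4;
* ``unetpp``          — nested dense skip pathways with deep-supervision
                        heads, averaged at inference.

Training is 2D and slice-based; the ``positive_slice_only`` flag restricts
the sample pool to slices whose mask contains at least one foreground
pixel, countering the extreme background imbalance of calcium masks.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .preprocess import ConfigError

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SegmentationModel",
    "DataError",
    "VARIANTS",
    "build_model",
    "count_parameters",
    "train",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("unet", "resunet", "attention_unet", "unetpp")


class DataError(ValueError):
    """The training data violates its contract."""


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "unet"
    depth: int = 4                # number of down-samplings -> depth+1 scales
    base_channels: int = 64
    in_channels: int = 1
    out_channels: int = 1
    attention_inner_divisor: int = 4   # gate inner channels = skip channels / this

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.base_channels < 1 or self.out_channels < 1:
            raise ConfigError("channel counts must be >= 1")

    @property
    def channels(self) -> tuple[int, ...]:
        """Per-scale channel schedule: base * 2**level."""
        return tuple(self.base_channels * 2 ** i for i in range(self.depth + 1))


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "dice_bce"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    positive_slice_only: bool = True
    augment: str = "none"         # or "flip"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.loss != "dice_bce" or self.optimizer != "adam":
            raise ConfigError("supported: loss='dice_bce', optimizer='adam'")
        if self.augment not in ("none", "flip"):
            raise ConfigError(f"unknown augment {self.augment!r}")


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class DoubleConv(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.relu(self.conv2(nn.relu(self.conv1(x))))


class ResDoubleConv(nn.Module):
    """Double conv with a residual shortcut; ReLU after the addition."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng)
        self.proj = nn.Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.conv2(nn.relu(self.conv1(x)))
        s = self.proj(x) if self.proj is not None else x
        return nn.relu(nn.add(h, s))


class AttentionGate(nn.Module):
    """Additive attention on a skip connection.

    Both the gating signal (upsampled decoder feature) and the skip carry
    ``channels`` channels; the inner dimension is ``channels // divisor``.
    """

    def __init__(self, channels: int, divisor: int, rng: np.random.Generator):
        inner = max(channels // divisor, 1)
        self.wg = nn.Conv2d(channels, inner, 1, rng)
        self.wx = nn.Conv2d(channels, inner, 1, rng)
        self.psi = nn.Conv2d(inner, 1, 1, rng)

    def __call__(self, g: nn.Tensor, x: nn.Tensor) -> nn.Tensor:
        a = nn.sigmoid(self.psi(nn.relu(nn.add(self.wg(g), self.wx(x)))))
        return nn.mul(x, a)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _UNetLike(nn.Module):
    """Shared encoder-decoder skeleton for unet / resunet / attention_unet."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        ch = cfg.channels
        block = ResDoubleConv if cfg.variant == "resunet" else DoubleConv
        self.enc = [block(cfg.in_channels if i == 0 else ch[i - 1], ch[i], rng)
                    for i in range(cfg.depth)]
        self.bottleneck = block(ch[cfg.depth - 1], ch[cfg.depth], rng)
        self.ups = [nn.ConvTranspose2d(ch[i + 1], ch[i], rng)
                    for i in reversed(range(cfg.depth))]
        self.dec = [block(2 * ch[i], ch[i], rng) for i in reversed(range(cfg.depth))]
        self.gates = ([AttentionGate(ch[i], cfg.attention_inner_divisor, rng)
                       for i in reversed(range(cfg.depth))]
                      if cfg.variant == "attention_unet" else None)
        self.head = nn.Conv2d(ch[0], cfg.out_channels, 1, rng)
        self.depth = cfg.depth

    def forward_logits(self, x: nn.Tensor) -> list[nn.Tensor]:
        skips = []
        h = x
        for enc in self.enc:
            h = enc(h)
            skips.append(h)
            h = nn.maxpool2x2(h)
        h = self.bottleneck(h)
        for k, (up, dec) in enumerate(zip(self.ups, self.dec)):
            skip = skips[self.depth - 1 - k]
            g = up(h)
            if self.gates is not None:
                skip = self.gates[k](g, skip)
            h = dec(nn.concat([g, skip]))
        return [self.head(h)]


class _UNetPP(nn.Module):
    """Nested dense skip pathways (node X[i][j]) with deep supervision."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        ch = cfg.channels
        d = cfg.depth
        self.depth = d
        self.enc = [DoubleConv(cfg.in_channels if i == 0 else ch[i - 1], ch[i], rng)
                    for i in range(d + 1)]
        # up[i][j] lifts X[i+1][j-1] to scale i; block[i][j] fuses
        # X[i][0..j-1] (j * ch[i]) with the upsampled feature (ch[i]).
        self.ups = {}
        self.blocks = {}
        for i in range(d):
            for j in range(1, d - i + 1):
                self.ups[(i, j)] = nn.ConvTranspose2d(ch[i + 1], ch[i], rng)
                self.blocks[(i, j)] = DoubleConv((j + 1) * ch[i], ch[i], rng)
        self._up_list = [self.ups[k] for k in sorted(self.ups)]
        self._block_list = [self.blocks[k] for k in sorted(self.blocks)]
        self.heads = [nn.Conv2d(ch[0], cfg.out_channels, 1, rng) for _ in range(d)]

    def forward_logits(self, x: nn.Tensor) -> list[nn.Tensor]:
        d = self.depth
        grid: dict[tuple[int, int], nn.Tensor] = {}
        h = x
        for i in range(d + 1):
            h = self.enc[i](h if i == 0 else nn.maxpool2x2(grid[(i - 1, 0)]))
            grid[(i, 0)] = h
        for j in range(1, d + 1):
            for i in range(0, d - j + 1):
                up = self.ups[(i, j)](grid[(i + 1, j - 1)])
                prev = [grid[(i, k)] for k in range(j)]
                grid[(i, j)] = self.blocks[(i, j)](nn.concat(prev + [up]))
        return [head(grid[(0, j + 1)]) for j, head in enumerate(self.heads)]


@dataclass
class SegmentationModel:
    """A built (possibly trained) 2D slice segmenter."""

    config: ModelConfig
    net: nn.Module
    seed: int
    loss_history: list[float] = field(default_factory=list)
    n_train_slices: int = 0

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def parameter_checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.net.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationModel:
    """Instantiate a variant with seeded He initialization."""
    rng = np.random.default_rng(seed)
    if config.variant == "unetpp":
        net = _UNetPP(config, rng)
    else:
        net = _UNetLike(config, rng)
    return SegmentationModel(config=config, net=net, seed=seed)


def count_parameters(model: SegmentationModel) -> int:
    """Exact count of trainable scalars."""
    return model.n_parameters()


def parameters_millions(model: SegmentationModel) -> float:
    return round(model.n_parameters() / 1e6, 2)


def _check_input(model: SegmentationModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:  # (C,H,W) -> batch of 1
        x = x[None]
    if x.ndim != 4 or x.shape[1] != model.config.in_channels:
        raise ValueError(
            f"expected (N,{model.config.in_channels},H,W) input, got {x.shape}"
        )
    f = 2 ** model.config.depth
    if x.shape[2] % f or x.shape[3] % f:
        raise ValueError(f"spatial size {x.shape[2:]} not divisible by {f}")
    return x


def predict_proba(model: SegmentationModel, slices: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probabilities for a stack of slices.

    Input ``(N, C, H, W)`` (or a single ``(C, H, W)`` slice); output
    ``(N, H, W)`` in [0, 1]. Deterministic. UNet++ averages the sigmoid
    outputs of its deep-supervision heads.
    """
    x = _check_input(model, slices)
    heads = model.net.forward_logits(nn.Tensor(x))
    probs = [1.0 / (1.0 + np.exp(-np.clip(h.data, -60, 60))) for h in heads]
    out = np.mean(probs, axis=0)
    return out[:, 0] if model.config.out_channels == 1 else out


def train(model: SegmentationModel,
          dataset: Sequence[tuple[np.ndarray, np.ndarray]],
          tc: TrainConfig = TrainConfig()) -> SegmentationModel:
    """Train in place; returns the model with its per-epoch loss history.

    ``dataset`` yields ``(input (C,H,W), binary mask (H,W))`` pairs on one
    grid. With ``positive_slice_only`` the pool is restricted to masks with
    foreground. Fixed ``tc.seed`` makes the run reproducible.
    """
    pairs = [(np.asarray(x, np.float32), np.asarray(y, np.float32)) for x, y in dataset]
    if not pairs:
        raise DataError("empty training dataset")
    if tc.positive_slice_only:
        pairs = [(x, y) for x, y in pairs if y.sum() > 0]
        if not pairs:
            raise DataError("positive-slice-only training requires >= 1 positive slice")

    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(model.net.parameters(), lr=tc.learning_rate)
    n = len(pairs)
    model.n_train_slices = n
    for _epoch in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            xb = np.stack([pairs[i][0] for i in idx])
            yb = np.stack([pairs[i][1] for i in idx])[:, None]
            if tc.augment == "flip":
                for k in range(len(idx)):
                    if rng.random() < 0.5:
                        xb[k] = xb[k, :, :, ::-1]
                        yb[k] = yb[k, :, :, ::-1]
                    if rng.random() < 0.5:
                        xb[k] = xb[k, :, ::-1, :]
                        yb[k] = yb[k, :, ::-1, :]
            xt = _check_input(model, xb)
            model.net.zero_grad()
            heads = model.net.forward_logits(nn.Tensor(xt, requires_grad=False))
            # mark graph trainable via parameters; loss per head, averaged
            losses_t = [nn.dice_bce_from_logits(h, yb) for h in heads]
            loss = losses_t[0] if len(losses_t) == 1 else nn.mean_tensors(losses_t)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_history.append(float(np.mean(losses)))
    return model


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path: str | Path) -> Path:
    """Single-file .npz archive with embedded config JSON."""
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.net.parameters())}
    meta = json.dumps({"config": asdict(model.config), "seed": model.seed,
                       "loss_history": model.loss_history})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **arrays)
    return path


def load_checkpoint(path: str | Path) -> SegmentationModel:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = ModelConfig(**meta["config"])
        model = build_model(cfg, seed=meta["seed"])
        params = model.net.parameters()
        for i, p in enumerate(params):
            stored = z[f"p{i}"]
            if stored.shape != p.data.shape:
                raise ValueError("checkpoint does not match the configured topology")
            p.data = stored.astype(np.float32)
        model.loss_history = list(meta["loss_history"])
    return model
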