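"""Encoder-decoder refinement of BIM permittivity reconstructions.

A small U-Net maps a blurry, artefact-laden permittivity map produced by
the quadratic-programming BIM onto a ground-truth-like map.  Contracting
path: per resolution level, two 3x3 convolutions each followed by batch
normalization and ReLU, then 2x2 max pooling with stride 2, doubling the
channel count at every reduction.  Expanding path: nearest-neighbour
upsampling followed by a 2x2 convolution halving the channels,
concatenation with the matching contracting feature map, and two 3x3
convolutions with ReLU.  A final 1x1 projection returns the
single-channel map.

Maps are normalised to [0, 1] by the assumed tissue permittivity range
before entering the network and de-normalised (and clipped back to the
range) on output.  The network refines permittivity only; conductivity
is regenerated afterwards from the refined map via the linear tissue
model in :mod:`mwtomo.metrics`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import nn
from .phantoms import EPS_R_RANGE

__all__ = [
    "RefinerConfig",
    "TrainingPair",
    "UNetRefiner",
    "TrainingError",
    "build_refiner",
    "train",
    "refine",
    "split_pairs",
    "make_training_set",
    "save_refiner",
    "load_refiner",
]


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class RefinerConfig:
    """Architecture and training settings for the refiner network."""

    input_size: int = 64
    depth: int = 4              # resolution levels, bottleneck included
    base_channels: int = 16
    seed: int = 0
    loss: str = "mse"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    split_fraction: float = 0.9
    upsample: str = "nearest"
    eps_range: tuple[float, float] = EPS_R_RANGE

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.input_size % (1 << (self.depth - 1)) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by "
                f"2^(depth-1) = {1 << (self.depth - 1)}"
            )
        if self.loss != "mse":
            raise ValueError("only squared-error loss is supported")
        if self.upsample != "nearest":
            raise ValueError("only nearest-neighbour upsampling is supported")

    def as_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "depth": self.depth,
            "base_channels": self.base_channels,
            "seed": self.seed,
            "loss": self.loss,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "split_fraction": self.split_fraction,
            "upsample": self.upsample,
            "eps_range": list(self.eps_range),
        }


@dataclass
class TrainingPair:
    """One (reconstruction, ground truth) permittivity pair."""

    input: np.ndarray
    target: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.input = np.asarray(self.input, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.input.shape != self.target.shape:
            raise ValueError("input and target must share shape")


def _double_conv_bn(in_ch: int, out_ch: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, 3, 1, rng), nn.BatchNorm2d(out_ch), nn.ReLU(),
        nn.Conv2d(out_ch, out_ch, 3, 1, rng), nn.BatchNorm2d(out_ch), nn.ReLU(),
    )


def _double_conv(in_ch: int, out_ch: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, 3, 1, rng), nn.ReLU(),
        nn.Conv2d(out_ch, out_ch, 3, 1, rng), nn.ReLU(),
    )


class UNetRefiner:
    """The contracting/expanding network with skip concatenations."""

    def __init__(self, config: RefinerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, base = config.depth, config.base_channels
        ch = [base * (1 << i) for i in range(d)]
        self.enc = [
            _double_conv_bn(1 if i == 0 else ch[i - 1], ch[i], rng)
            for i in range(d - 1)
        ]
        self.pools = [nn.MaxPool2() for _ in range(d - 1)]
        self.bottleneck = _double_conv_bn(ch[d - 2], ch[d - 1], rng)
        self.ups = []
        self.dec = []
        for i in range(d - 2, -1, -1):
            self.ups.append(nn.Sequential(
                nn.UpsampleNN2(),
                nn.Conv2d(ch[i + 1], ch[i], 2, ((0, 1), (0, 1)), rng),
            ))
            self.dec.append(_double_conv(2 * ch[i], ch[i], rng))
        self.head = nn.Conv2d(base, 1, 1, 0, rng)
        self._skips = None

    # -- plumbing ---------------------------------------------------------
    def _modules(self):
        return [*self.enc, *self.pools, self.bottleneck, *self.ups, *self.dec,
                self.head]

    def parameters(self):
        return [p for m in self._modules() for p in m.parameters()]

    def gradients(self):
        return [g for m in self._modules() for g in m.gradients()]

    def state_arrays(self) -> list[np.ndarray]:
        """All learned arrays plus batch-norm running statistics."""
        arrays = list(self.parameters())
        for m in self._modules():
            stack = m.layers if isinstance(m, nn.Sequential) else [m]
            for layer in stack:
                if isinstance(layer, nn.BatchNorm2d):
                    arrays.extend([layer.run_mean, layer.run_var])
        return arrays

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        if train:
            self._skips = skips
        return self.head.forward(x, train)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(grad)
        skip_grads = [None] * len(self.dec)
        for i in range(len(self.dec) - 1, -1, -1):
            grad = self.dec[i].backward(grad)
            n_skip = self._skips[len(self.enc) - 1 - i].shape[1]
            skip_grads[i] = grad[:, :n_skip]
            grad = self.ups[i].backward(grad[:, n_skip:])
        grad = self.bottleneck.backward(grad)
        for i in range(len(self.enc) - 1, -1, -1):
            grad = self.pools[i].backward(grad)
            grad = grad + skip_grads[len(self.enc) - 1 - i]
            grad = self.enc[i].backward(grad)
        self._skips = None

    # -- user-facing inference -------------------------------------------
    def _normalize(self, eps_map: np.ndarray) -> np.ndarray:
        lo, hi = self.config.eps_range
        return (eps_map - lo) / (hi - lo)

    def _denormalize(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.config.eps_range
        return np.clip(x * (hi - lo) + lo, lo, hi)

    def refine(self, eps_map: np.ndarray) -> np.ndarray:
        """Refine one M x M permittivity map (deterministic, clipped)."""
        eps_map = np.asarray(eps_map, dtype=float)
        m = self.config.input_size
        if eps_map.shape != (m, m):
            raise ValueError(f"expected a {m} x {m} map, got {eps_map.shape}")
        x = self._normalize(eps_map)[None, None]
        out = self.forward(x, train=False)[0, 0]
        return self._denormalize(out)


def build_refiner(config: RefinerConfig) -> UNetRefiner:
    """Build the refiner; same config and seed give identical weights."""
    return UNetRefiner(config)


def refine(model: UNetRefiner, bim_map: np.ndarray) -> np.ndarray:
    """Single forward pass through a trained refiner."""
    return model.refine(bim_map)


def split_pairs(
    pairs: Sequence[TrainingPair], fraction: float, seed: int
) -> tuple[list[TrainingPair], list[TrainingPair]]:
    """Deterministic seeded shuffle into train/validation lists.

    The training set takes floor(fraction * n) pairs.
    """
    idx = np.random.default_rng(seed).permutation(len(pairs))
    n_train = int(np.floor(fraction * len(pairs)))
    train_idx, val_idx = idx[:n_train], idx[n_train:]
    return [pairs[i] for i in train_idx], [pairs[i] for i in val_idx]


def train(
    model: UNetRefiner,
    pairs: Sequence[TrainingPair],
    config: Optional[RefinerConfig] = None,
) -> dict:
    """Train the refiner on permittivity pairs.

    Pixel-wise squared-error loss on the normalised maps, Adam updates,
    seeded minibatch order.  Returns ``{"train_loss": [...],
    "val_loss": [...]}`` with one entry per epoch.  Raises
    :class:`TrainingError` if the loss becomes non-finite.
    """
    cfg = config or model.config
    if len(pairs) < 2:
        raise ValueError("need at least two training pairs")
    tr, va = split_pairs(pairs, cfg.split_fraction, cfg.seed)
    if not tr:
        raise ValueError("split fraction leaves no training pairs")

    def stack(ps):
        x = np.stack([model._normalize(p.input) for p in ps])[:, None]
        y = np.stack([model._normalize(p.target) for p in ps])[:, None]
        return x, y

    xtr, ytr = stack(tr)
    xva, yva = stack(va) if va else (None, None)
    opt = nn.Adam(model.parameters(), model.gradients(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xtr))
        total = 0.0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = xtr[sel], ytr[sel]
            out = model.forward(xb, train=True)
            diff = out - yb
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged at epoch {epoch}")
            model.backward(2.0 * diff / diff.size)
            opt.step()
            total += loss * len(sel)
        history["train_loss"].append(total / len(xtr))
        if xva is not None:
            val_out = model.forward(xva, train=False)
            history["val_loss"].append(float(np.mean((val_out - yva) ** 2)))
    return history


def make_training_set(
    phantom_specs: Sequence[dict],
    reconstruct_fn: Callable[[dict], tuple[np.ndarray, np.ndarray]],
) -> list[TrainingPair]:
    """Assemble training pairs by reconstructing a phantom sweep.

    ``phantom_specs`` is the deterministic sweep description (one dict per
    phantom); ``reconstruct_fn`` maps a spec to ``(bim_eps_map,
    truth_eps_map)``.  A failed reconstruction skips the pair with a
    warning rather than aborting the sweep.
    """
    pairs: list[TrainingPair] = []
    for spec in phantom_specs:
        try:
            bim_map, truth_map = reconstruct_fn(spec)
        except Exception as exc:  # noqa: BLE001 - sweep must survive one failure
            warnings.warn(f"reconstruction failed for {spec}: {exc}", stacklevel=2)
            continue
        pairs.append(TrainingPair(bim_map, truth_map, provenance=dict(spec)))
    return pairs


def save_refiner(model: UNetRefiner, path) -> None:
    """Checkpoint: one npz of all arrays plus the architecture config."""
    import json

    arrays = {f"a{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __config__=json.dumps(model.config.as_dict()), **arrays)


def load_refiner(path) -> UNetRefiner:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        cfg_dict["eps_range"] = tuple(cfg_dict["eps_range"])
        model = UNetRefiner(RefinerConfig(**cfg_dict))
        for i, arr in enumerate(model.state_arrays()):
            arr[...] = data[f"a{i}"]
    return model
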