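"""Residual 3D classifier built from depthwise-separable convolutions.

The classifier stacks three residual blocks, each composed of two
depthwise-separable convolutions with PReLU activations; each block halves
every spatial side, so valid input sides are multiples of 8. A flatten and a
single linear head produce two logits (healthy vs AD-like). Depthwise
separation brings a KxKxK convolution from C*O*K^3 weights down to
C*(K^3 + O), which matters when the inputs are whole 3D volumes.

Training is plain Adam on two-class cross-entropy — deliberately ordinary,
because the uncertainty machinery is added after training by perturbing
only the head (see :mod:`bayeshead.bayesify`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DivergedTrainingError
from .layers import Adam, Linear, ResidualBlock, cross_entropy, softmax
from .synthetic import LabeledDataset

__all__ = [
    "ConvSpec",
    "NetworkSpec",
    "TrainConfig",
    "TrainedNetwork",
    "count_separable_params",
    "build_network",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ConvSpec:
    """One separable convolution: C input channels, O output, kernel K."""

    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1 or self.kernel < 1:
            raise ValueError("channels and kernel must be positive")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")


def count_separable_params(C: int, K: int, O: int, with_bias: bool = False) -> int:
    """Weight count of a depthwise-separable convolution: C(K^3 + O).

    The depthwise stage has C*K^3 weights, the pointwise stage C*O; biases
    (one per depthwise channel plus one per output channel) add C + O.
    """
    if C < 1 or K < 1 or O < 1:
        raise ValueError("C, K and O must be positive integers")
    n = C * K**3 + C * O
    if with_bias:
        n += C + O
    return n


@dataclass(frozen=True)
class NetworkSpec:
    input_shape: tuple[int, int, int] = (32, 32, 32)
    block_channels: tuple[int, int, int] = (4, 8, 16)
    n_classes: int = 2
    kernel: int = 3

    def __post_init__(self):
        if len(self.input_shape) != 3 or any(s % 8 != 0 or s < 8 for s in self.input_shape):
            raise ValueError(
                f"input sides must be positive multiples of 8 (three halvings), got {self.input_shape}"
            )
        if len(self.block_channels) != 3 or any(c < 1 for c in self.block_channels):
            raise ValueError("block_channels must be three positive integers")

    @property
    def flatten_size(self) -> int:
        d, h, w = (s // 8 for s in self.input_shape)
        return self.block_channels[-1] * d * h * w


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    epochs: int = 5
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class TrainedNetwork:
    """Architecture + parameters; 'trained' once :func:`train` has run.

    ``head`` is the final linear layer whose optimal weights w* later become
    the means of the stochastic head.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        chans = (1,) + tuple(spec.block_channels)
        self.blocks = [
            ResidualBlock(chans[i], chans[i + 1], spec.kernel, stride=2, rng=rng)
            for i in range(3)
        ]
        self.head = Linear(spec.flatten_size, spec.n_classes, rng)
        self.training_log: list[dict] = []

    # ---- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray):
        if x.ndim != 5 or x.shape[1] != 1 or tuple(x.shape[2:]) != tuple(self.spec.input_shape):
            raise ValueError(
                f"expected input (B, 1, {self.spec.input_shape}), got {x.shape}"
            )

    def features(self, x: np.ndarray) -> np.ndarray:
        """Body forward pass: (B, 1, D, H, W) -> flattened (B, F)."""
        self._check_input(x)
        h = x
        for b in self.blocks:
            h = b.forward(h)
        self._feat_shape = h.shape
        return h.reshape(h.shape[0], -1)

    def forward(self, x: np.ndarray, head_weight=None, head_bias=None) -> np.ndarray:
        """Logits; the head parameters may be overridden by a sampled draw."""
        return self.head.forward(self.features(x), weight=head_weight, bias=head_bias)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(logits); returns d(loss)/d(input)."""
        g = self.head.backward(glogits).reshape(self._feat_shape)
        for b in reversed(self.blocks):
            g = b.backward(g)
        return g

    def input_gradient(self, x: np.ndarray, target_class: int, head_weight=None, head_bias=None) -> np.ndarray:
        """Gradient of the target-class logit w.r.t. each input volume."""
        if not 0 <= target_class < self.spec.n_classes:
            raise ValueError(f"target_class {target_class} out of range")
        logits = self.forward(x, head_weight=head_weight, head_bias=head_bias)
        g = np.zeros_like(logits)
        g[:, target_class] = 1.0
        return self.backward(g)

    # ---- parameters ---------------------------------------------------------
    def params(self):
        ps = []
        for b in self.blocks:
            ps += b.params()
        ps += self.head.params()
        return ps

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


def build_network(spec: NetworkSpec, seed: int = 0) -> TrainedNetwork:
    """Deterministically initialised (untrained) network for ``spec``."""
    return TrainedNetwork(spec, seed=seed)


def train(net: TrainedNetwork, data: LabeledDataset, cfg: TrainConfig) -> TrainedNetwork:
    """Fit the network on the dataset's train partition.

    Adam on two-class cross-entropy, per-epoch shuffling from ``cfg.seed``;
    the run is deterministic for a fixed seed. Appends one log entry per
    epoch with the mean batch loss and training accuracy.
    """
    train_part = data.partition("train")
    if len(train_part) == 0:
        raise ValueError("dataset has an empty train split")
    X = train_part.stack()
    y = train_part.labels
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), lr=cfg.learning_rate)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses, n_correct = [], 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(X[idx])
            loss, glogits = cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise DivergedTrainingError(epoch=epoch, loss=loss)
            opt.zero_grad()
            net.backward(glogits)
            opt.step()
            losses.append(loss)
            n_correct += int(np.sum(logits.argmax(axis=1) == y[idx]))
        net.training_log.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "accuracy": n_correct / len(X),
            }
        )
    return net


# ---- checkpointing ---------------------------------------------------------

def save_checkpoint(net: TrainedNetwork, path) -> None:
    """Self-describing archive: spec + seed + training log + all weights."""
    meta = {
        "spec": {
            "input_shape": list(net.spec.input_shape),
            "block_channels": list(net.spec.block_channels),
            "n_classes": net.spec.n_classes,
            "kernel": net.spec.kernel,
        },
        "seed": net.seed,
        "training_log": net.training_log,
    }
    arrays = {f"param_{i:04d}": p.value for i, p in enumerate(net.params())}
    with open(path, "wb") as f:
        np.savez(f, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TrainedNetwork:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        spec = NetworkSpec(
            input_shape=tuple(meta["spec"]["input_shape"]),
            block_channels=tuple(meta["spec"]["block_channels"]),
            n_classes=meta["spec"]["n_classes"],
            kernel=meta["spec"]["kernel"],
        )
        net = TrainedNetwork(spec, seed=meta["seed"])
        net.training_log = meta["training_log"]
        for i, p in enumerate(net.params()):
            p.value[...] = npz[f"param_{i:04d}"]
    return net
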