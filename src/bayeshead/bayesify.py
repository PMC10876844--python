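"""Post-hoc conversion of a trained classifier into a stochastic one.

The idea: after ordinary training the head weights sit at (or near) a loss
minimum w*. Replace each head weight by a narrow Gaussian N(w*, s) and run
inference many times, sampling a fresh head each pass — an ensemble of
networks in the neighbourhood of the optimum. Averaging the per-pass softmax
probabilities approximates the Bayesian predictive mean

    p(y | D) = E_{w ~ p(w|D)} [ p(y | w) ],

and the per-class standard deviation over passes measures how stable the
prediction is under small weight perturbations. Inputs whose prediction
flips easily (e.g. near the decision boundary, or off the training
distribution) get a high standard deviation, which downstream modules use
as a rejection signal. Only the final linear layer is stochastic; the
convolutional body stays frozen, so the expensive body forward pass can be
computed once per volume and reused across all draws.

Randomness is counter-based: the head draw for (seed, sample i, draw j)
comes from ``np.random.SeedSequence([seed, i, j])``, so results do not
depend on batching or evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import softmax
from .network import TrainedNetwork
from .synthetic import Volume

__all__ = [
    "StochasticHead",
    "MCConfig",
    "MCPrediction",
    "StochasticNetwork",
    "convert",
    "sample_forward",
    "mc_predict",
]

DEFAULT_PERTURBATION_SD = 0.01
DEFAULT_N_SAMPLES = 100


@dataclass
class StochasticHead:
    """Gaussian head: mean weights w* (the trained values) and scale s."""

    weight_mean: np.ndarray  # (n_classes, n_features)
    bias_mean: np.ndarray  # (n_classes,)
    s: float

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("perturbation scale s must be non-negative")

    def draw(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """One Gaussian draw of the full head (weights and biases)."""
        w = self.weight_mean + self.s * rng.standard_normal(self.weight_mean.shape)
        b = self.bias_mean + self.s * rng.standard_normal(self.bias_mean.shape)
        return w, b


@dataclass(frozen=True)
class MCConfig:
    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class MCPrediction:
    """Monte-Carlo predictive summary for one volume."""

    mean_probs: np.ndarray
    std_probs: np.ndarray
    predicted_class: int
    uncertainty: float  # std of the predicted (argmax-mean) class
    n_samples: int


class StochasticNetwork:
    """A frozen trained body paired with a Gaussian-perturbed head."""

    def __init__(self, net: TrainedNetwork, head: StochasticHead):
        self.net = net
        self.head = head

    @property
    def s(self) -> float:
        return self.head.s

    def mean_network(self) -> TrainedNetwork:
        """The deterministic network at the Gaussian means — the original."""
        return self.net

    def features(self, x: np.ndarray) -> np.ndarray:
        return self.net.features(x)

    def forward_with_draw(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        w, b = self.head.draw(rng)
        return self.net.forward(x, head_weight=w, head_bias=b)


def convert(net: TrainedNetwork, s: float = DEFAULT_PERTURBATION_SD) -> StochasticNetwork:
    """Turn a trained network's head into Gaussians N(w*, s); body untouched.

    Lossless and reversible: the mean network is the original network.
    """
    if s < 0:
        raise ValueError("perturbation scale s must be non-negative")
    head = StochasticHead(
        weight_mean=net.head.weight.value.copy(),
        bias_mean=net.head.bias.value.copy(),
        s=float(s),
    )
    return StochasticNetwork(net, head)


def _as_batch(volume) -> np.ndarray:
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if data.ndim == 3:
        data = data[None, None]
    return data


def sample_forward(stoch_net: StochasticNetwork, volume, seed: int) -> np.ndarray:
    """One stochastic forward pass: sample a head, run it, softmax.

    Deterministic for a fixed seed.
    """
    x = _as_batch(volume)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    logits = stoch_net.forward_with_draw(x, rng)
    return softmax(logits)[0]


def mc_predict(stoch_net: StochasticNetwork, volumes, cfg: MCConfig = MCConfig()) -> list[MCPrediction]:
    """N stochastic passes per volume; summarise with mean and std.

    The body features are computed once per volume; each of the N draws is a
    cheap affine map plus softmax. Standard deviations use the population
    convention (divisor N), so a single draw has std 0. The per-volume
    uncertainty is the std of the class with the highest mean probability.
    """
    preds = []
    for i, vol in enumerate(volumes):
        phi = stoch_net.features(_as_batch(vol))  # (1, F)
        if stoch_net.head.s == 0.0:
            # zero-variance degeneracy: every draw equals the mean network
            h = stoch_net.head
            mean = softmax(phi @ h.weight_mean.T + h.bias_mean)[0]
            std = np.zeros_like(mean)
        else:
            probs = np.empty((cfg.n_samples, stoch_net.head.bias_mean.size))
            for j in range(cfg.n_samples):
                rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), i, j]))
                w, b = stoch_net.head.draw(rng)
                probs[j] = softmax(phi @ w.T + b)[0]
            mean = probs.mean(axis=0)
            std = probs.std(axis=0)  # ddof=0
        k = int(mean.argmax())
        preds.append(
            MCPrediction(
                mean_probs=mean,
                std_probs=std,
                predicted_class=k,
                uncertainty=float(std[k]),
                n_samples=cfg.n_samples,
            )
        )
    return preds
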