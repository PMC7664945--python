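"""Stacked sparse auto-encoders with a Softmax head, and supervised fine-tuning.

Two (or more) auto-encoders are pretrained greedily: the first on the raw
features, each subsequent one on the previous encoder's output, so the
feature width shrinks gradually.  Their encoder halves are then stacked under
a Softmax classifier and the whole network is fine-tuned by full-batch
gradient descent on the categorical cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._errors import DimensionError, NumericError
from .sae import AEWeights, SparseAEConfig, encode, train_sae

__all__ = [
    "StackedNetwork",
    "LabelSet",
    "softmax_forward",
    "greedy_pretrain",
    "build_network",
    "finetune",
    "predict_network",
]


@dataclass
class LabelSet:
    """Integer class labels 0..M-1 with their one-hot encoding."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer vector")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_classes
        ):
            raise ValueError(
                f"labels must lie in 0..{self.n_classes - 1}; got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def one_hot(self) -> np.ndarray:
        out = np.zeros((self.labels.size, self.n_classes))
        out[np.arange(self.labels.size), self.labels] = 1.0
        return out

    def subset(self, idx: np.ndarray) -> "LabelSet":
        return LabelSet(self.labels[idx], self.n_classes)


@dataclass
class StackedNetwork:
    """Ordered encoder halves plus the Softmax classification layer."""

    encoders: list[AEWeights]
    softmax_weights: np.ndarray  # (n_classes, last_hidden)
    softmax_bias: np.ndarray  # (n_classes,)
    n_classes: int

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        self.softmax_weights = np.asarray(self.softmax_weights, dtype=float)
        self.softmax_bias = np.asarray(self.softmax_bias, dtype=float)
        widths = self.feature_dims
        for prev, nxt in zip(self.encoders[:-1], self.encoders[1:]):
            if nxt.input_size != prev.hidden_size:
                raise DimensionError(
                    f"encoder chain broken: {prev.hidden_size} -> "
                    f"{nxt.input_size} expected to match"
                )
        if self.softmax_weights.shape != (self.n_classes, widths[-1]):
            raise DimensionError(
                f"softmax_weights shape {self.softmax_weights.shape} does not "
                f"match (n_classes={self.n_classes}, last_hidden={widths[-1]})"
            )
        if self.softmax_bias.shape != (self.n_classes,):
            raise DimensionError(
                f"softmax_bias shape {self.softmax_bias.shape} does not match "
                f"n_classes={self.n_classes}"
            )

    @property
    def feature_dims(self) -> list[int]:
        """Layer widths from input through every encoding."""
        dims = [self.encoders[0].input_size] if self.encoders else []
        dims += [enc.hidden_size for enc in self.encoders]
        return dims

    def copy(self) -> "StackedNetwork":
        return StackedNetwork(
            [e.copy() for e in self.encoders],
            self.softmax_weights.copy(),
            self.softmax_bias.copy(),
            self.n_classes,
        )


def softmax_forward(features: np.ndarray, network: StackedNetwork) -> np.ndarray:
    """Class probabilities from the deepest encoded features.

    Computed with the max-subtraction trick so rows are stable and sum to 1.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    d = network.softmax_weights.shape[1]
    if features.shape[1] != d:
        raise DimensionError(
            f"features have width {features.shape[1]} but the Softmax layer "
            f"expects {d}"
        )
    logits = features @ network.softmax_weights.T + network.softmax_bias
    if not np.all(np.isfinite(logits)):
        raise NumericError("softmax logits are non-finite")
    logits = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(logits)
    return ez / ez.sum(axis=1, keepdims=True)


def encode_stack(x: np.ndarray, encoders: list[AEWeights]) -> np.ndarray:
    """Push data through every encoder half in order."""
    h = np.atleast_2d(np.asarray(x, dtype=float))
    for enc in encoders:
        h = encode(h, enc)
    return h


def greedy_pretrain(
    x: np.ndarray, *cfgs: SparseAEConfig
) -> tuple[list[AEWeights], np.ndarray]:
    """Layer-wise unsupervised pretraining.

    Each auto-encoder is trained on the previous layer's encoding, reducing
    the feature count gradually.  Returns the trained encoders and the
    deepest encoded features (width = last config's hidden_size).
    """
    if not cfgs:
        raise ValueError("at least one SparseAEConfig is required")
    encoders: list[AEWeights] = []
    h = np.atleast_2d(np.asarray(x, dtype=float))
    for cfg in cfgs:
        w = train_sae(h, cfg)
        encoders.append(w)
        h = encode(h, w)
    return encoders, h


def build_network(
    encoders: list[AEWeights], n_classes: int
) -> StackedNetwork:
    """Stack pretrained encoders under a zero-initialized Softmax layer.

    Zero Softmax weights give uniform initial class probabilities and a
    deterministic, convex warm start for fine-tuning.
    """
    last = encoders[-1].hidden_size
    return StackedNetwork(
        [e.copy() for e in encoders],
        np.zeros((n_classes, last)),
        np.zeros(n_classes),
        n_classes,
    )


def _forward_all(
    network: StackedNetwork, x: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Activations of every layer (input first) and the class probabilities."""
    acts = [np.atleast_2d(np.asarray(x, dtype=float))]
    for enc in network.encoders:
        acts.append(expit(acts[-1] @ enc.encoder_weights.T + enc.encoder_bias))
    probs = softmax_forward(acts[-1], network)
    return acts, probs


def cross_entropy(probs: np.ndarray, y: LabelSet) -> float:
    """Mean negative log-probability of the true class."""
    p = np.clip(probs[np.arange(y.n_samples), y.labels], 1e-300, None)
    return float(-np.mean(np.log(p)))


def finetune(
    network: StackedNetwork,
    x: np.ndarray,
    y: LabelSet,
    epochs: int = 400,
    lr: float = 1.0,
    momentum: float = 0.9,
    seed: int = 0,
) -> StackedNetwork:
    """Supervised backpropagation through the whole stack.

    Full-batch heavy-ball gradient descent on the categorical cross-entropy
    of the Softmax outputs.  The momentum term is needed in practice: the
    sparsity-pretrained hidden units start nearly saturated at the target
    activation, and plain small-step descent moves too slowly through two
    sigmoid layers to recover class information.  The parameters with the
    lowest loss seen during the run are returned, so the training loss never
    ends above its starting value.  ``seed`` is accepted for interface
    symmetry; the update is deterministic.
    """
    del seed  # full-batch descent from a fixed start point needs no randomness
    if epochs < 0:
        raise ValueError(f"epochs must be >= 0, got {epochs}")
    if not 0.0 <= momentum < 1.0:
        raise ValueError(f"momentum must lie in [0, 1), got {momentum}")
    net = network.copy()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if y.n_samples != n:
        raise DimensionError(
            f"{n} samples but {y.n_samples} labels"
        )

    best = net.copy()
    _, probs = _forward_all(net, x)
    best_loss = cross_entropy(probs, y)
    target = y.one_hot
    velocity: list[np.ndarray] | None = None

    for _ in range(epochs):
        acts, probs = _forward_all(net, x)
        dlogits = (probs - target) / n  # (n, M)
        g_sw = dlogits.T @ acts[-1]
        g_sb = dlogits.sum(axis=0)
        dh = dlogits @ net.softmax_weights
        # backprop through each encoder half, deepest first
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        for li in range(len(net.encoders) - 1, -1, -1):
            h = acts[li + 1]
            dz = dh * h * (1.0 - h)
            grads.append((dz.T @ acts[li], dz.sum(axis=0)))
            dh = dz @ net.encoders[li].encoder_weights
        grads.reverse()

        params = [net.softmax_weights, net.softmax_bias]
        flat_grads = [g_sw, g_sb]
        for enc, (gw, gb) in zip(net.encoders, grads):
            params += [enc.encoder_weights, enc.encoder_bias]
            flat_grads += [gw, gb]
        if velocity is None:
            velocity = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, flat_grads, velocity):
            v *= momentum
            v -= lr * g
            p += v

        _, probs = _forward_all(net, x)
        loss = cross_entropy(probs, y)
        if not np.isfinite(loss):
            raise NumericError("fine-tuning loss became non-finite")
        if loss < best_loss:
            best_loss = loss
            best = net.copy()
    return best


def predict_network(network: StackedNetwork, x: np.ndarray) -> np.ndarray:
    """Class-probability matrix Z_hat for raw inputs (rows sum to 1)."""
    _, probs = _forward_all(network, x)
    return probs
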