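"""Single sparse auto-encoder: forward passes, regularized cost, training.

The auto-encoder maps an input vector ``x`` (features scaled to [0, 1]) through
a logistic-sigmoid hidden layer and reconstructs it with a second sigmoid
layer.  Training minimizes a reconstruction cost augmented with an L2 weight
penalty and a KL-divergence sparsity penalty that pushes the mean activation
of every hidden unit toward a target sparsity proportion ``rho``:

    E = (1/n) * sum_samples ||x - x_hat||^2
        + l2_coeff * Omega_weights
        + sparsity_coeff * Omega_sparsity

where ``Omega_weights`` is half the sum of squared entries of both weight
matrices (biases excluded) and ``Omega_sparsity`` sums, over hidden units,
the KL divergence between Bernoulli(rho) and Bernoulli(rho_hat_i), with
rho_hat_i the mean activation of unit i over the training batch.

Training is deterministic: weights are initialized from a seeded uniform
Glorot scheme and optimized full-batch with L-BFGS using the analytic
gradient, capped at ``max_epochs`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from ._errors import DimensionError, NumericError, OptimizerDivergenceError

__all__ = [
    "SparseAEConfig",
    "AEWeights",
    "encode",
    "decode",
    "l2_weight_penalty",
    "kl_sparsity",
    "sae_cost",
    "train_sae",
]

#: activations are clipped into [EPS, 1 - EPS] before any logarithm
EPS = 1e-10


@dataclass(frozen=True)
class SparseAEConfig:
    """Hyperparameters of one sparse auto-encoder layer.

    Parameters
    ----------
    hidden_size
        Number of hidden units (the encoded feature width).
    max_epochs
        Iteration cap for the full-batch optimizer.
    l2_coeff
        Coefficient ``lambda`` of the L2 weight penalty.
    sparsity_coeff
        Coefficient ``beta`` of the KL sparsity penalty.
    sparsity_proportion
        Target mean activation ``rho`` of each hidden unit, in (0, 1).
    seed
        Seed for the weight initialization.
    """

    hidden_size: int
    max_epochs: int = 400
    l2_coeff: float = 1e-3
    sparsity_coeff: float = 1.0
    sparsity_proportion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError(f"hidden_size must be >= 1, got {self.hidden_size}")
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.l2_coeff < 0:
            raise ValueError(f"l2_coeff must be >= 0, got {self.l2_coeff}")
        if self.sparsity_coeff < 0:
            raise ValueError(
                f"sparsity_coeff must be >= 0, got {self.sparsity_coeff}"
            )
        if not 0.0 < self.sparsity_proportion < 1.0:
            raise ValueError(
                "sparsity_proportion must lie strictly in (0, 1), got "
                f"{self.sparsity_proportion}"
            )


@dataclass
class AEWeights:
    """Encoder/decoder weights and biases of one auto-encoder.

    ``encoder_weights`` has shape (hidden_size, input_size); the decoder
    mirrors it untied with shape (input_size, hidden_size).
    """

    encoder_weights: np.ndarray
    encoder_bias: np.ndarray
    decoder_weights: np.ndarray
    decoder_bias: np.ndarray

    def __post_init__(self) -> None:
        self.encoder_weights = np.asarray(self.encoder_weights, dtype=float)
        self.encoder_bias = np.asarray(self.encoder_bias, dtype=float)
        self.decoder_weights = np.asarray(self.decoder_weights, dtype=float)
        self.decoder_bias = np.asarray(self.decoder_bias, dtype=float)
        h, n = self.encoder_weights.shape
        if self.encoder_bias.shape != (h,):
            raise DimensionError(
                f"encoder_bias shape {self.encoder_bias.shape} does not match "
                f"hidden size {h}"
            )
        if self.decoder_weights.shape != (n, h):
            raise DimensionError(
                f"decoder_weights shape {self.decoder_weights.shape} does not "
                f"match (input_size={n}, hidden_size={h})"
            )
        if self.decoder_bias.shape != (n,):
            raise DimensionError(
                f"decoder_bias shape {self.decoder_bias.shape} does not match "
                f"input size {n}"
            )
        for name, arr in (
            ("encoder_weights", self.encoder_weights),
            ("encoder_bias", self.encoder_bias),
            ("decoder_weights", self.decoder_weights),
            ("decoder_bias", self.decoder_bias),
        ):
            if not np.all(np.isfinite(arr)):
                raise NumericError(f"{name} contains non-finite entries")

    @property
    def input_size(self) -> int:
        return self.encoder_weights.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.encoder_weights.shape[0]

    def copy(self) -> "AEWeights":
        return AEWeights(
            self.encoder_weights.copy(),
            self.encoder_bias.copy(),
            self.decoder_weights.copy(),
            self.decoder_bias.copy(),
        )


def encode(x: np.ndarray, w: AEWeights) -> np.ndarray:
    """Hidden activations sigmoid(W1 x + b1), shape (n_samples, hidden_size)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != w.input_size:
        raise DimensionError(
            f"input has {x.shape[1]} features but the encoder expects "
            f"{w.input_size} (x shape {x.shape}, W shape "
            f"{w.encoder_weights.shape})"
        )
    return expit(x @ w.encoder_weights.T + w.encoder_bias)


def decode(h: np.ndarray, w: AEWeights) -> np.ndarray:
    """Reconstruction sigmoid(W2 h + b2), shape (n_samples, input_size)."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[1] != w.hidden_size:
        raise DimensionError(
            f"hidden activations have {h.shape[1]} columns but the decoder "
            f"expects {w.hidden_size} (h shape {h.shape}, W shape "
            f"{w.decoder_weights.shape})"
        )
    return expit(h @ w.decoder_weights.T + w.decoder_bias)


def l2_weight_penalty(w: AEWeights) -> float:
    """Half the sum of squared entries of both weight matrices (no biases)."""
    return 0.5 * (
        float(np.sum(w.encoder_weights**2)) + float(np.sum(w.decoder_weights**2))
    )


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """Summed KL divergence between Bernoulli(rho) and each Bernoulli(rho_hat_i).

    ``rho_hat`` entries are clipped into [EPS, 1 - EPS] before the logs; values
    outside [0, 1] (or non-finite) raise :class:`NumericError`.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie strictly in (0, 1), got {rho}")
    rho_hat = np.asarray(rho_hat, dtype=float)
    if not np.all(np.isfinite(rho_hat)) or np.any(rho_hat < 0) or np.any(rho_hat > 1):
        raise NumericError(
            "rho_hat entries must be finite and within [0, 1]; got "
            f"min={np.min(rho_hat)}, max={np.max(rho_hat)}"
        )
    rh = np.clip(rho_hat, EPS, 1.0 - EPS)
    return float(
        np.sum(rho * np.log(rho / rh) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rh)))
    )


def _forward(x: np.ndarray, w: AEWeights) -> tuple[np.ndarray, np.ndarray]:
    h = expit(x @ w.encoder_weights.T + w.encoder_bias)
    xhat = expit(h @ w.decoder_weights.T + w.decoder_bias)
    return h, xhat


def sae_cost(
    x: np.ndarray, w: AEWeights, cfg: SparseAEConfig
) -> tuple[float, AEWeights]:
    """Regularized reconstruction cost and its analytic gradient.

    Returns ``(E, grad)`` where ``grad`` is an :class:`AEWeights` holding
    dE/dW1, dE/db1, dE/dW2, dE/db2.  The cost is

        E = (1/n) sum_i ||x_i - x_hat_i||^2
            + l2_coeff * Omega_weights + sparsity_coeff * Omega_sparsity
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != w.input_size:
        raise DimensionError(
            f"data has {x.shape[1]} features, auto-encoder expects {w.input_size}"
        )
    n = x.shape[0]
    lam, beta, rho = cfg.l2_coeff, cfg.sparsity_coeff, cfg.sparsity_proportion

    h, xhat = _forward(x, w)
    resid = xhat - x
    recon = float(np.sum(resid**2)) / n
    omega_w = l2_weight_penalty(w)
    rho_hat = np.clip(h.mean(axis=0), EPS, 1.0 - EPS)
    omega_s = kl_sparsity(rho, rho_hat)

    cost = recon + lam * omega_w + beta * omega_s
    if not np.isfinite(cost):
        parts = {"reconstruction": recon, "l2": omega_w, "sparsity": omega_s}
        bad = [k for k, v in parts.items() if not np.isfinite(v)]
        raise NumericError(f"sae_cost diverged in term(s): {', '.join(bad) or 'sum'}")

    # backprop: d(recon)/d(xhat) = 2 resid / n, through the output sigmoid
    dz2 = (2.0 / n) * resid * xhat * (1.0 - xhat)          # (n, N)
    g_dec_w = dz2.T @ h + lam * w.decoder_weights          # (N, H)
    g_dec_b = dz2.sum(axis=0)                              # (N,)

    # hidden-layer signal: reconstruction path + sparsity penalty path
    dh = dz2 @ w.decoder_weights                           # (n, H)
    dkl_drho = beta * (-(rho / rho_hat) + (1.0 - rho) / (1.0 - rho_hat))
    dh = dh + dkl_drho / n                                 # rho_hat is a mean over n
    dz1 = dh * h * (1.0 - h)                               # (n, H)
    g_enc_w = dz1.T @ x + lam * w.encoder_weights          # (H, N)
    g_enc_b = dz1.sum(axis=0)                              # (H,)

    grad = AEWeights(g_enc_w, g_enc_b, g_dec_w, g_dec_b)
    return cost, grad


def _pack(w: AEWeights) -> np.ndarray:
    return np.concatenate(
        [
            w.encoder_weights.ravel(),
            w.encoder_bias,
            w.decoder_weights.ravel(),
            w.decoder_bias,
        ]
    )


def _unpack(theta: np.ndarray, input_size: int, hidden_size: int) -> AEWeights:
    n, h = input_size, hidden_size
    i = 0
    enc_w = theta[i : i + h * n].reshape(h, n)
    i += h * n
    enc_b = theta[i : i + h]
    i += h
    dec_w = theta[i : i + n * h].reshape(n, h)
    i += n * h
    dec_b = theta[i : i + n]
    return AEWeights(enc_w, enc_b, dec_w, dec_b)


def init_weights(input_size: int, hidden_size: int, seed: int) -> AEWeights:
    """Seeded symmetric-uniform (Glorot) initialization; biases start at zero."""
    rng = np.random.default_rng(seed)
    r = np.sqrt(6.0 / (input_size + hidden_size))
    enc_w = rng.uniform(-r, r, size=(hidden_size, input_size))
    dec_w = rng.uniform(-r, r, size=(input_size, hidden_size))
    return AEWeights(enc_w, np.zeros(hidden_size), dec_w, np.zeros(input_size))


def train_sae(x: np.ndarray, cfg: SparseAEConfig) -> AEWeights:
    """Train one sparse auto-encoder on features scaled to [0, 1].

    Deterministic full-batch L-BFGS minimization of :func:`sae_cost` with the
    analytic gradient, capped at ``cfg.max_epochs`` iterations.  The returned
    weights never cost more than the initial ones.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 1:
        raise ValueError("training data must contain at least one sample")
    if np.any(x < -1e-9) or np.any(x > 1.0 + 1e-9):
        raise ValueError("training features must be scaled to [0, 1]")
    n_feat = x.shape[1]
    w0 = init_weights(n_feat, cfg.hidden_size, cfg.seed)
    theta0 = _pack(w0)

    increase_streak = [0]
    last_cost = [np.inf]

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w = _unpack(theta, n_feat, cfg.hidden_size)
        c, g = sae_cost(x, w, cfg)
        return c, _pack(g)

    def callback(theta: np.ndarray) -> None:
        c, _ = fun(theta)
        if c > last_cost[0]:
            increase_streak[0] += 1
            if increase_streak[0] >= 10:
                raise OptimizerDivergenceError(
                    "sae_cost increased for 10 consecutive iterations"
                )
        else:
            increase_streak[0] = 0
        last_cost[0] = c

    initial_cost, _ = fun(theta0)
    res = minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": cfg.max_epochs},
    )
    if res.fun > initial_cost:  # pragma: no cover - L-BFGS accepts only decreases
        return w0
    return _unpack(res.x, n_feat, cfg.hidden_size)
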