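"""Linear output calibration Z = A*Z_hat + B*X + e fitted with PSO.

The classifier's continuous class-probability outputs ``Z_hat`` are corrected
toward the one-hot targets ``Q`` by a linear model: ``A`` is a diagonal M x M
matrix rescaling each class score, ``B`` an M x N matrix mixing in the object
features ``X``, and ``e`` an M-vector offset.  The parameters are found by
particle swarm search minimizing the mean squared error between the corrected
outputs and the targets.  One particle is seeded at the identity transform
(A = I, B = 0, e = 0), so the fitted model can never do worse on the training
targets than the uncalibrated network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import DimensionError
from .pso import PSOConfig, pso_minimize

__all__ = [
    "LinearPostModel",
    "FitResult",
    "linear_transform",
    "mse_cost",
    "fit_linear_post",
    "classify",
]

FEATURE_SOURCES = ("original_input", "deepest_encoding")


@dataclass
class LinearPostModel:
    """Diagonal-A linear correction of classifier outputs.

    ``feature_source`` records which representation the ``X`` term expects:
    the raw input features or the deepest auto-encoder encoding.
    """

    a_diag: np.ndarray  # (M,)
    b: np.ndarray  # (M, N)
    e: np.ndarray  # (M,)
    feature_source: str = "deepest_encoding"

    def __post_init__(self) -> None:
        self.a_diag = np.asarray(self.a_diag, dtype=float)
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.e = np.asarray(self.e, dtype=float)
        m = self.a_diag.size
        if self.b.shape[0] != m or self.e.shape != (m,):
            raise DimensionError(
                f"inconsistent model dims: a_diag {self.a_diag.shape}, "
                f"b {self.b.shape}, e {self.e.shape}"
            )
        if self.feature_source not in FEATURE_SOURCES:
            raise ValueError(
                f"feature_source must be one of {FEATURE_SOURCES}, got "
                f"{self.feature_source!r}"
            )
        for name, arr in (("a_diag", self.a_diag), ("b", self.b), ("e", self.e)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def n_classes(self) -> int:
        return self.a_diag.size

    @property
    def n_features(self) -> int:
        return self.b.shape[1]

    @classmethod
    def identity(
        cls, n_classes: int, n_features: int,
        feature_source: str = "deepest_encoding",
    ) -> "LinearPostModel":
        return cls(
            np.ones(n_classes),
            np.zeros((n_classes, n_features)),
            np.zeros(n_classes),
            feature_source,
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "a_diag": self.a_diag.tolist(),
            "b": self.b.ravel().tolist(),  # row-major
            "e": self.e.tolist(),
            "feature_source": self.feature_source,
            "n_classes": self.n_classes,
            "n_features": self.n_features,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearPostModel":
        doc = json.loads(Path(path).read_text())
        m, n = doc["n_classes"], doc["n_features"]
        return cls(
            np.asarray(doc["a_diag"]),
            np.asarray(doc["b"]).reshape(m, n),
            np.asarray(doc["e"]),
            doc["feature_source"],
        )


@dataclass
class FitResult:
    """Outcome of one PSO fit of the calibration model."""

    model: LinearPostModel
    train_mse: float
    history: np.ndarray = field(repr=False)
    n_examples: int = 0


def linear_transform(
    z_hat: np.ndarray, x: np.ndarray, model: LinearPostModel
) -> np.ndarray:
    """Corrected outputs Z = A Z_hat + B x + e per sample (A diagonal)."""
    z_hat = np.atleast_2d(np.asarray(z_hat, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if z_hat.shape[1] != model.n_classes:
        raise DimensionError(
            f"z_hat has {z_hat.shape[1]} columns, model expects "
            f"M={model.n_classes}"
        )
    if x.shape[1] != model.n_features:
        raise DimensionError(
            f"x has {x.shape[1]} columns, model expects N={model.n_features}"
        )
    return z_hat * model.a_diag + x @ model.b.T + model.e


def mse_cost(z: np.ndarray, q: np.ndarray) -> float:
    """Mean over all entries of the squared difference between outputs and
    targets (samples x classes)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if z.shape != q.shape:
        raise DimensionError(f"shape mismatch: z {z.shape} vs q {q.shape}")
    return float(np.mean((z - q) ** 2))


def pack_params(model: LinearPostModel) -> np.ndarray:
    """Flatten to the PSO search vector [a_diag, B row-major, e]."""
    return np.concatenate([model.a_diag, model.b.ravel(), model.e])


def unpack_params(
    vec: np.ndarray, n_classes: int, n_features: int,
    feature_source: str = "deepest_encoding",
) -> LinearPostModel:
    m, n = n_classes, n_features
    vec = np.asarray(vec, dtype=float)
    if vec.size != m + m * n + m:
        raise DimensionError(
            f"parameter vector of length {vec.size} does not match "
            f"M + M*N + M = {m + m * n + m}"
        )
    return LinearPostModel(
        vec[:m], vec[m : m + m * n].reshape(m, n), vec[m + m * n :],
        feature_source,
    )


def fit_linear_post(
    z_hat: np.ndarray,
    x: np.ndarray,
    q: np.ndarray,
    cfg: PSOConfig,
    feature_source: str = "deepest_encoding",
) -> FitResult:
    """Fit A, B, e by PSO minimization of the training MSE.

    The search space has dimension M + M*N + M.  The first particle starts at
    the identity transform, so ``train_mse`` is never above the MSE of the
    uncalibrated outputs.
    """
    z_hat = np.atleast_2d(np.asarray(z_hat, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if not (z_hat.shape[0] == x.shape[0] == q.shape[0]):
        raise DimensionError(
            f"sample counts differ: z_hat {z_hat.shape[0]}, x {x.shape[0]}, "
            f"q {q.shape[0]}"
        )
    if z_hat.shape != q.shape:
        raise DimensionError(f"z_hat {z_hat.shape} and q {q.shape} must match")
    m, n = z_hat.shape[1], x.shape[1]

    def cost(vec: np.ndarray) -> float:
        model = unpack_params(vec, m, n, feature_source)
        return mse_cost(linear_transform(z_hat, x, model), q)

    identity = pack_params(LinearPostModel.identity(m, n, feature_source))
    best_vec, best_cost, history = pso_minimize(
        cost, identity.size, cfg, seed_positions=identity[None, :]
    )
    model = unpack_params(best_vec, m, n, feature_source)
    return FitResult(
        model=model,
        train_mse=float(best_cost),
        history=history,
        n_examples=z_hat.shape[0],
    )


def classify(z: np.ndarray) -> np.ndarray:
    """Class decision per row: argmax, ties broken toward the lowest index."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return np.argmax(z, axis=1)
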