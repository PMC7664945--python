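"""Independent oracles used by the test suite.

These are deliberately separate routes from the package implementation:
closed-form least squares, finite differences, and nearest-centroid
classification, so agreement with the package is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def ols_minimum_mse(z_hat: np.ndarray, x: np.ndarray, q: np.ndarray) -> float:
    """Global minimum of the calibration MSE over diagonal-A linear models.

    With A diagonal the classes decouple: for each class c the corrected
    output is a linear function of [z_hat[:, c], x, 1], so per-class ordinary
    least squares gives the exact global optimum of the mean squared error.
    """
    total = 0.0
    for c in range(z_hat.shape[1]):
        design = np.column_stack([z_hat[:, c], x, np.ones(len(x))])
        beta, *_ = np.linalg.lstsq(design, q[:, c], rcond=None)
        resid = q[:, c] - design @ beta
        total += float(np.sum(resid**2))
    return total / q.size


def finite_difference_gradient(fun, theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of a flat vector."""
    grad = np.zeros_like(theta)
    for i in range(theta.size):
        up = theta.copy()
        down = theta.copy()
        up[i] += eps
        down[i] -= eps
        grad[i] = (fun(up) - fun(down)) / (2 * eps)
    return grad


def nearest_centroid_accuracy(
    x: np.ndarray, labels: np.ndarray, n_classes: int
) -> float:
    """Training accuracy of a plain nearest-centroid rule."""
    centroids = np.vstack(
        [x[labels == c].mean(axis=0) for c in range(n_classes)]
    )
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float(np.mean(np.argmin(d2, axis=1) == labels))
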