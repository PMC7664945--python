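"""Seeded synthetic data emulating the shapes of the benchmark datasets.

Three dataset presets mirror the studies the framework targets:

* ``epilepsy-like`` — 200 samples x 4096 features, two balanced classes,
  the shape of a two-group EEG epilepsy recording set;
* ``spectf-like`` — 267 x 44, two imbalanced classes (187 normal / 80
  abnormal), the shape of the SPECTF heart-imaging feature set;
* ``arrhythmia-like`` — 450 x 279, 16 unevenly populated classes with 5%
  missing entries, the shape of the UCI cardiac-arrhythmia table.

Features are Gaussian class-conditionals around class centroids separated by
a configurable Euclidean distance — a deliberate simplification that
exercises every pipeline stage deterministically.  A noiseless linear
fixture supports testing the output-calibration model against a closed-form
least-squares oracle.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .linear_post import LinearPostModel, linear_transform
from .stack import LabelSet

__all__ = [
    "SynthSpec",
    "DATASET_PRESETS",
    "make_classification_dataset",
    "make_linear_fixture",
    "write_dataset_csv",
]


@dataclass(frozen=True)
class SynthSpec:
    """Shape and structure of one synthetic classification dataset.

    ``separation`` is the Euclidean distance between class centroids;
    ``noise_sd`` the per-feature within-class standard deviation.  With
    separation s and noise 1 the two-class Bayes error is Phi(-s/2).
    """

    n_samples: int
    n_features: int
    n_classes: int = 2
    class_proportions: tuple[float, ...] | None = None
    separation: float = 4.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("n_samples and n_features must be >= 1")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.separation < 0:
            raise ValueError(f"separation must be >= 0, got {self.separation}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(
                f"missing_rate must lie in [0, 1), got {self.missing_rate}"
            )
        if self.class_proportions is not None:
            props = np.asarray(self.class_proportions, dtype=float)
            if props.size != self.n_classes:
                raise ValueError(
                    f"{props.size} proportions for {self.n_classes} classes"
                )
            if np.any(props <= 0) or not np.isclose(props.sum(), 1.0):
                raise ValueError("proportions must be positive and sum to 1")

    @property
    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_proportions, dtype=float)


# uneven 16-class weights loosely following a dominant-class clinical table,
# floored so every class survives a stratified 70/30 split
_ARRHYTHMIA_WEIGHTS = (
    245, 44, 15, 15, 13, 25, 4, 4, 9, 50, 4, 4, 4, 5, 5, 22,
)

DATASET_PRESETS: dict[str, SynthSpec] = {
    "epilepsy-like": SynthSpec(
        n_samples=200, n_features=4096, n_classes=2,
        class_proportions=(0.5, 0.5), separation=6.0, noise_sd=1.0,
    ),
    "spectf-like": SynthSpec(
        n_samples=267, n_features=44, n_classes=2,
        class_proportions=(187 / 267, 80 / 267), separation=4.0, noise_sd=1.0,
    ),
    "arrhythmia-like": SynthSpec(
        n_samples=450, n_features=279, n_classes=16,
        class_proportions=tuple(
            w / sum(_ARRHYTHMIA_WEIGHTS) for w in _ARRHYTHMIA_WEIGHTS
        ),
        separation=6.0, noise_sd=1.0, missing_rate=0.05,
    ),
}


def _class_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding so counts sum exactly to n."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder)[:short]:
        counts[idx] += 1
    if np.any(counts == 0):
        bad = np.flatnonzero(counts == 0).tolist()
        raise ValueError(
            f"proportions give zero samples for class(es) {bad} at n={n}"
        )
    return counts


def _centroids(
    n_classes: int, n_features: int, separation: float, rng: np.random.Generator
) -> np.ndarray:
    """Class centroids at pairwise Euclidean distance ``separation``.

    Two classes sit at +/- (s/2) u along a random unit direction; more
    classes are placed on mutually orthonormal random directions scaled to
    s/sqrt(2), which makes every pairwise distance exactly s.
    """
    if n_classes == 2:
        u = rng.normal(size=n_features)
        u /= np.linalg.norm(u)
        return np.vstack([-0.5 * separation * u, 0.5 * separation * u])
    g = rng.normal(size=(n_features, n_classes))
    q, _ = np.linalg.qr(g)
    return (separation / np.sqrt(2.0)) * q.T[:n_classes]


def make_classification_dataset(spec: SynthSpec) -> tuple[np.ndarray, LabelSet]:
    """Gaussian class-conditional features with optional missing entries.

    Missing entries are NaN; the loader's median imputation mirrors the
    UCI "?" convention.  Deterministic per seed; label counts follow the
    requested proportions exactly (largest-remainder rounding).
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec.n_samples, spec.proportions)
    labels = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(labels)
    centroids = _centroids(spec.n_classes, spec.n_features, spec.separation, rng)
    x = centroids[labels] + spec.noise_sd * rng.normal(
        size=(spec.n_samples, spec.n_features)
    )
    if spec.missing_rate > 0:
        mask = rng.random(x.shape) < spec.missing_rate
        x[mask] = np.nan
    return x, LabelSet(labels, spec.n_classes)


def make_linear_fixture(
    m: int,
    M: int,
    N: int,
    coeff_scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, LinearPostModel]:
    """Continuous targets generated by a known calibration model.

    Draws classifier-like outputs ``z_hat`` on the probability simplex
    (Dirichlet), features ``x`` uniform in [0, 1], model coefficients
    uniform in +/- coeff_scale, and emits
    ``q = A* z_hat + B* x + e* + Gaussian noise``.  Returns
    ``(z_hat, x, q, true_model)``.
    """
    if min(m, M, N) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    z_hat = rng.dirichlet(np.ones(M), size=m)
    x = rng.random((m, N))
    model = LinearPostModel(
        a_diag=rng.uniform(-coeff_scale, coeff_scale, size=M),
        b=rng.uniform(-coeff_scale, coeff_scale, size=(M, N)),
        e=rng.uniform(-coeff_scale, coeff_scale, size=M),
        feature_source="original_input",
    )
    q = linear_transform(z_hat, x, model)
    if noise_sd > 0:
        q = q + noise_sd * rng.normal(size=q.shape)
    return z_hat, x, q, model


def get_preset(name: str, seed: int | None = None) -> SynthSpec:
    """Named dataset preset, optionally reseeded."""
    if name not in DATASET_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(DATASET_PRESETS)}"
        )
    spec = DATASET_PRESETS[name]
    if seed is not None:
        spec = replace(spec, seed=seed)
    return spec


def write_dataset_csv(x: np.ndarray, y: LabelSet, path: str | Path) -> None:
    """Write features plus a final label column; NaN becomes the "?" marker."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        for row, label in zip(np.atleast_2d(x), y.labels):
            cells = ["?" if np.isnan(v) else repr(float(v)) for v in row]
            writer.writerow(cells + [int(label)])
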