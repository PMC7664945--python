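"""Confusion-matrix diagnostics, repeated random subsampling, paired t-test.

Ten statistics are reported for every evaluation: recall (TPR), TNR,
precision (PPV), NPV, FPR, FDR, miss rate, accuracy, F1 and the Matthews
correlation coefficient.  For binary problems class 1 ("abnormal") is the
positive class; for multiclass problems each statistic is macro-averaged
over one-vs-rest binary reductions so all 16 arrhythmia-style classes weigh
equally.

Model comparison follows a repeated random-subsampling protocol: the data
are split into stratified train/test halves several times (five by default),
the full pipeline is retrained per repeat, and the per-repeat metric vectors
of the raw network versus the calibrated network are compared with a
two-tailed paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

from ._errors import DegenerateInputError, StratificationError
from .linear_post import classify, fit_linear_post, linear_transform, mse_cost
from .preprocessing import MinMaxScaler
from .stack import (
    LabelSet,
    build_network,
    encode_stack,
    finetune,
    greedy_pretrain,
    predict_network,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io import RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "RepeatProtocol",
    "EvalResult",
    "compute_metrics",
    "paired_t_test",
    "stratified_split",
    "repeated_holdout_eval",
]

METRIC_NAMES = (
    "recall",
    "tnr",
    "precision",
    "npv",
    "fpr",
    "fdr",
    "miss_rate",
    "accuracy",
    "f1",
    "mcc",
)


@dataclass
class MetricReport:
    """The ten confusion-derived statistics for one evaluation run."""

    recall: float
    tnr: float
    precision: float
    npv: float
    fpr: float
    fdr: float
    miss_rate: float
    accuracy: float
    f1: float
    mcc: float
    n_test: int = 0
    per_class: list["MetricReport"] | None = field(default=None, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in METRIC_NAMES])


@dataclass(frozen=True)
class RepeatProtocol:
    """Repeated random-subsampling settings."""

    n_repeats: int = 5
    train_fraction: float = 0.5
    stratified: bool = True
    seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        if self.seeds is not None and len(self.seeds) != self.n_repeats:
            raise ValueError(
                f"{len(self.seeds)} seeds given for {self.n_repeats} repeats"
            )

    def repeat_seeds(self, base_seed: int) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return [(base_seed + 1000003 * i) % (2**31 - 1) for i in range(self.n_repeats)]


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; reporting 0", what)
        return 0.0
    return num / den


def _binary_report(tp: int, fn: int, tn: int, fp: int) -> MetricReport:
    recall = _safe_div(tp, tp + fn, "recall")
    tnr = _safe_div(tn, tn + fp, "TNR")
    precision = _safe_div(tp, tp + fp, "precision")
    npv = _safe_div(tn, tn + fn, "NPV")
    fpr = 1.0 - tnr
    fdr = 1.0 - precision
    miss = 1.0 - recall
    acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy")
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "F1")
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den, "MCC")
    return MetricReport(
        recall, tnr, precision, npv, fpr, fdr, miss, acc, f1, mcc,
        n_test=tp + fn + tn + fp,
    )


def compute_metrics(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> MetricReport:
    """Confusion-matrix statistics for one set of predictions.

    Binary problems treat class 1 as positive; multiclass problems report
    macro-averaged one-vs-rest values with the per-class reports attached.
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    if y.max() >= n_classes or p.max() >= n_classes or y.min() < 0 or p.min() < 0:
        raise ValueError("labels must lie in 0..n_classes-1")

    if n_classes == 2:
        tp = int(np.sum((y == 1) & (p == 1)))
        fn = int(np.sum((y == 1) & (p == 0)))
        tn = int(np.sum((y == 0) & (p == 0)))
        fp = int(np.sum((y == 0) & (p == 1)))
        return _binary_report(tp, fn, tn, fp)

    per_class = []
    for c in range(n_classes):
        tp = int(np.sum((y == c) & (p == c)))
        fn = int(np.sum((y == c) & (p != c)))
        fp = int(np.sum((y != c) & (p == c)))
        tn = int(np.sum((y != c) & (p != c)))
        per_class.append(_binary_report(tp, fn, tn, fp))
    macro = np.mean([r.as_vector() for r in per_class], axis=0)
    report = MetricReport(*macro, n_test=y.size, per_class=per_class)
    return report


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t-test on matched samples.

    Returns ``(t, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` on the
    differences ``d = a - b`` and n-1 degrees of freedom.  Zero-variance
    differences raise :class:`DegenerateInputError` rather than fabricating
    an infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"a and b must be equal-length vectors, got {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError(
            "paired differences have zero variance; the t statistic is undefined"
        )
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p


def stratified_split(
    labels: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
    n_classes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split keeping every class on both sides.

    A class with fewer than 2 members (or a per-class allocation that would
    empty either side) raises :class:`StratificationError`.
    """
    labels = np.asarray(labels, dtype=int)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in range(n_classes):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise StratificationError(
                f"class {c} has {idx.size} sample(s); cannot appear in both "
                "train and test splits"
            )
        perm = rng.permutation(idx)
        k = int(round(train_fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


@dataclass
class EvalResult:
    """Averaged and per-repeat reports for raw vs calibrated predictions."""

    raw_mean: MetricReport
    post_mean: MetricReport
    per_repeat_raw: list[MetricReport]
    per_repeat_post: list[MetricReport]
    t_statistic: float
    p_value: float
    train_mses: list[float] = field(default_factory=list)


def _mean_report(reports: list[MetricReport]) -> MetricReport:
    mat = np.mean([r.as_vector() for r in reports], axis=0)
    return MetricReport(*mat, n_test=int(np.mean([r.n_test for r in reports])))


def train_pipeline(
    x_train: np.ndarray,
    y_train: LabelSet,
    config: "RunConfig",
    repeat_seed: int,
):
    """Pretrain, fine-tune and calibrate on one training split.

    Returns ``(network, fit_result)`` where the calibration model was fitted
    on the training split's outputs only.
    """
    from dataclasses import replace

    ae_cfgs = [
        replace(c, seed=(c.seed + repeat_seed) % (2**31 - 1))
        for c in config.ae_configs
    ]
    encoders, encoded = greedy_pretrain(x_train, *ae_cfgs)
    network = build_network(encoders, y_train.n_classes)
    network = finetune(
        network, x_train, y_train,
        epochs=config.finetune_epochs, lr=config.finetune_lr,
        momentum=config.finetune_momentum, seed=repeat_seed,
    )
    z_hat = predict_network(network, x_train)
    if config.feature_source == "deepest_encoding":
        feats = encode_stack(x_train, network.encoders)
    else:
        feats = x_train
    pso_cfg = config.pso_for_repeat(repeat_seed)
    fit = fit_linear_post(
        z_hat, feats, y_train.one_hot, pso_cfg,
        feature_source=config.feature_source,
    )
    return network, fit


def _calibration_features(network, x: np.ndarray, feature_source: str) -> np.ndarray:
    if feature_source == "deepest_encoding":
        return encode_stack(x, network.encoders)
    return x


def repeated_holdout_eval(
    x: np.ndarray,
    y: LabelSet,
    config: "RunConfig",
    protocol: RepeatProtocol | None = None,
) -> EvalResult:
    """Run the full repeated random-subsampling comparison.

    Per repeat: stratified split, min-max scaling fitted on the training
    rows, greedy pretraining, fine-tuning, calibration fitted on training
    outputs, then both the raw and the calibrated predictions are scored on
    the untouched test split.  The paired t-test matches every per-repeat
    metric value of the raw system with its calibrated counterpart.
    """
    protocol = protocol or config.protocol
    x = np.atleast_2d(np.asarray(x, dtype=float))
    raw_reports: list[MetricReport] = []
    post_reports: list[MetricReport] = []
    train_mses: list[float] = []

    for rep, seed in enumerate(protocol.repeat_seeds(config.seed)):
        rng = np.random.default_rng(seed)
        if protocol.stratified:
            tr, te = stratified_split(y.labels, protocol.train_fraction, rng, y.n_classes)
        else:
            perm = rng.permutation(y.n_samples)
            k = int(round(protocol.train_fraction * y.n_samples))
            tr, te = np.sort(perm[:k]), np.sort(perm[k:])

        scaler = MinMaxScaler().fit(x[tr])
        x_tr = scaler.transform(x[tr])
        x_te = scaler.transform(x[te])
        y_tr, y_te = y.subset(tr), y.subset(te)

        network, fit = train_pipeline(x_tr, y_tr, config, seed)
        train_mses.append(fit.train_mse)

        z_hat_te = predict_network(network, x_te)
        raw_pred = classify(z_hat_te)
        feats_te = _calibration_features(network, x_te, config.feature_source)
        z_corr = linear_transform(z_hat_te, feats_te, fit.model)
        post_pred = classify(z_corr)

        raw_reports.append(compute_metrics(y_te.labels, raw_pred, y.n_classes))
        post_reports.append(compute_metrics(y_te.labels, post_pred, y.n_classes))
        logger.info(
            "repeat %d: raw ACC %.4f, calibrated ACC %.4f (train MSE %.5f)",
            rep, raw_reports[-1].accuracy, post_reports[-1].accuracy, fit.train_mse,
        )

    raw_vec = np.concatenate([r.as_vector() for r in raw_reports])
    post_vec = np.concatenate([r.as_vector() for r in post_reports])
    try:
        t, p = paired_t_test(raw_vec, post_vec)
    except DegenerateInputError:
        # identical metric tables on every repeat: no evidence of a difference
        logger.warning("raw and calibrated metrics are identical on every repeat")
        t, p = 0.0, 1.0
    return EvalResult(
        raw_mean=_mean_report(raw_reports),
        post_mean=_mean_report(post_reports),
        per_repeat_raw=raw_reports,
        per_repeat_post=post_reports,
        t_statistic=t,
        p_value=p,
        train_mses=train_mses,
    )
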