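"""Metric battery, paired t-test and the repeated-holdout protocol."""

import numpy as np
import pytest
from scipy import stats as sps

from saepso import (
    DegenerateInputError,
    MetricReport,
    RepeatProtocol,
    StratificationError,
    compute_metrics,
    paired_t_test,
)
from saepso.metrics import METRIC_NAMES, stratified_split


def random_binary_predictions(rng, n=60):
    y = rng.integers(0, 2, size=n)
    p = rng.integers(0, 2, size=n)
    return y, p


class TestComputeMetricsBinary:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        r = compute_metrics(y, y, 2)
        for name in ("recall", "tnr", "precision", "npv", "accuracy", "f1", "mcc"):
            assert getattr(r, name) == 1.0
        assert r.fpr == r.fdr == r.miss_rate == 0.0

    def test_worked_confusion_case(self):
        # TP=45, FN=5, TN=40, FP=10
        y = np.array([1] * 50 + [0] * 50)
        p = np.array([1] * 45 + [0] * 5 + [0] * 40 + [1] * 10)
        r = compute_metrics(y, p, 2)
        assert r.recall == pytest.approx(0.9)
        assert r.precision == pytest.approx(45 / 55)
        assert r.accuracy == pytest.approx(0.85)
        assert r.mcc == pytest.approx(1750.0 / np.sqrt(6187500.0), rel=1e-12)

    def test_anti_perfect_balanced(self):
        y = np.array([0, 0, 1, 1])
        p = 1 - y
        r = compute_metrics(y, p, 2)
        assert r.accuracy == 0.0
        assert r.mcc == -1.0

    def test_identities_hold_on_random_inputs(self, rng):
        for _ in range(100):
            y, p = random_binary_predictions(rng)
            r = compute_metrics(y, p, 2)
            assert r.fpr == pytest.approx(1.0 - r.tnr, abs=1e-12)
            assert r.fdr == pytest.approx(1.0 - r.precision, abs=1e-12)
            assert r.miss_rate == pytest.approx(1.0 - r.recall, abs=1e-12)
            vec = r.as_vector()
            assert np.all(vec[:9] >= 0) and np.all(vec[:9] <= 1)
            assert -1.0 <= r.mcc <= 1.0

    def test_agrees_with_sklearn_on_random_confusions(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(100):
            y, p = random_binary_predictions(rng)
            if len(np.unique(p)) < 2 or len(np.unique(y)) < 2:
                continue
            r = compute_metrics(y, p, 2)
            assert r.accuracy == pytest.approx(sk.accuracy_score(y, p))
            assert r.recall == pytest.approx(sk.recall_score(y, p))
            assert r.precision == pytest.approx(
                sk.precision_score(y, p, zero_division=0)
            )
            assert r.f1 == pytest.approx(sk.f1_score(y, p))
            assert r.mcc == pytest.approx(sk.matthews_corrcoef(y, p), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics([], [], 2)


class TestComputeMetricsMulticlass:
    def test_macro_average_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            y = rng.integers(0, 4, size=80)
            p = rng.integers(0, 4, size=80)
            r = compute_metrics(y, p, 4)
            assert r.recall == pytest.approx(
                sk.recall_score(y, p, average="macro", zero_division=0)
            )
            assert r.precision == pytest.approx(
                sk.precision_score(y, p, average="macro", zero_division=0)
            )
            assert r.f1 == pytest.approx(
                sk.f1_score(y, p, average="macro", zero_division=0)
            )

    def test_per_class_reports_attached(self, rng):
        y = rng.integers(0, 3, size=40)
        p = rng.integers(0, 3, size=40)
        r = compute_metrics(y, p, 3)
        assert r.per_class is not None and len(r.per_class) == 3
        assert r.recall == pytest.approx(
            np.mean([c.recall for c in r.per_class])
        )

    def test_sixteen_class_identities(self, rng):
        y = rng.integers(0, 16, size=200)
        p = rng.integers(0, 16, size=200)
        r = compute_metrics(y, p, 16)
        assert r.fpr == pytest.approx(1.0 - r.tnr, abs=1e-12)
        assert r.miss_rate == pytest.approx(1.0 - r.recall, abs=1e-12)


class TestPairedTTest:
    def test_matches_closed_form_and_reference(self, rng):
        for _ in range(20):
            a = rng.normal(size=12)
            b = a + rng.normal(scale=0.5, size=12)
            t, p = paired_t_test(a, b)
            d = a - b
            expected_t = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(len(d)))
            assert t == pytest.approx(expected_t, abs=1e-12)
            ref = sps.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_p_values_roughly_uniform(self, rng):
        # under H0 the p-value should not concentrate near 0
        ps = []
        for _ in range(200):
            a = rng.normal(size=10)
            b = a + rng.normal(scale=1.0, size=10)
            ps.append(paired_t_test(a, b)[1])
        assert 0.25 < np.mean(ps) < 0.75

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_antisymmetry(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


class TestStratifiedSplit:
    def test_preserves_class_counts(self, rng):
        labels = np.repeat([0, 1], [50, 50])
        tr, te = stratified_split(labels, 0.5, np.random.default_rng(0), 2)
        assert len(tr) == len(te) == 50
        assert np.sum(labels[tr] == 0) == 25
        assert np.sum(labels[te] == 1) == 25
        assert len(np.intersect1d(tr, te)) == 0

    def test_singleton_class_raises(self):
        with pytest.raises(StratificationError, match="class 1"):
            stratified_split(np.array([0, 0, 0, 1]), 0.5,
                             np.random.default_rng(0), 2)

    def test_every_class_on_both_sides(self, rng):
        labels = rng.integers(0, 5, size=60)
        labels[:10] = np.arange(5).repeat(2)  # ensure >= 2 per class
        tr, te = stratified_split(labels, 0.7, np.random.default_rng(1), 5)
        for c in range(5):
            assert np.any(labels[tr] == c)
            assert np.any(labels[te] == c)


class TestRepeatProtocol:
    def test_explicit_seeds_respected(self):
        proto = RepeatProtocol(n_repeats=3, seeds=(5, 6, 7))
        assert proto.repeat_seeds(0) == [5, 6, 7]

    def test_derived_seeds_distinct_and_bounded(self):
        proto = RepeatProtocol(n_repeats=5)
        seeds = proto.repeat_seeds(123)
        assert len(set(seeds)) == 5
        assert all(0 <= s < 2**31 for s in seeds)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            RepeatProtocol(n_repeats=0)
        with pytest.raises(ValueError):
            RepeatProtocol(train_fraction=1.0)
        with pytest.raises(ValueError):
            RepeatProtocol(n_repeats=2, seeds=(1,))


class TestRepeatedHoldout:
    @pytest.fixture
    def tiny_config(self):
        from saepso import PSOConfig, RunConfig, SparseAEConfig

        return RunConfig(
            ae_configs=(
                SparseAEConfig(6, 30, 1e-3, 0.5, 0.2, seed=0),
                SparseAEConfig(4, 30, 1e-3, 0.5, 0.2, seed=1),
            ),
            pso=PSOConfig(n_particles=15, max_iter=20, seed=0),
            protocol=RepeatProtocol(n_repeats=1, train_fraction=0.5),
            finetune_epochs=80,
            finetune_lr=0.5,
            seed=0,
        )

    def test_single_repeat_mean_equals_report(self, separable_binary, tiny_config):
        from saepso import repeated_holdout_eval

        x, y = separable_binary
        res = repeated_holdout_eval(x, y, tiny_config)
        assert len(res.per_repeat_raw) == 1
        assert np.allclose(
            res.raw_mean.as_vector(), res.per_repeat_raw[0].as_vector()
        )
        assert np.allclose(
            res.post_mean.as_vector(), res.per_repeat_post[0].as_vector()
        )

    def test_calibration_never_hurts_training_mse(self, separable_binary, tiny_config):
        from dataclasses import replace

        from saepso import repeated_holdout_eval

        x, y = separable_binary
        cfg = replace(tiny_config, protocol=RepeatProtocol(2, 0.5))
        res = repeated_holdout_eval(x, y, cfg)
        assert all(m >= 0.0 for m in res.train_mses)
        assert len(res.per_repeat_raw) == 2

    def test_multiclass_pipeline_reports_macro_metrics(self, tiny_config):
        from dataclasses import replace

        from saepso import SynthSpec, make_classification_dataset, repeated_holdout_eval

        spec = SynthSpec(n_samples=80, n_features=12, n_classes=4,
                         separation=6.0, noise_sd=1.0, seed=11,
                         missing_rate=0.0)
        x, y = make_classification_dataset(spec)
        cfg = replace(tiny_config, protocol=RepeatProtocol(1, 0.5))
        res = repeated_holdout_eval(x, y, cfg)
        assert res.raw_mean.per_class is None  # means carry no per-class list
        assert res.per_repeat_raw[0].per_class is not None
        assert len(res.per_repeat_raw[0].per_class) == 4
        assert 0.0 <= res.post_mean.accuracy <= 1.0

    def test_stratification_error_propagates(self, tiny_config, rng):
        from saepso import LabelSet, repeated_holdout_eval

        x = rng.random((5, 6))
        y = LabelSet([0, 0, 0, 0, 1], 2)
        with pytest.raises(StratificationError):
            repeated_holdout_eval(x, y, tiny_config)
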