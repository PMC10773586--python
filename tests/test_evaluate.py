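"""Segment metrics, event detection latency, and the two experiment drivers."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix

from topoeeg import (
    ClassifierConfig,
    ConfusionCounts,
    compute_metrics,
    event_detection,
    run_experiment1,
    run_experiment2,
)
from topoeeg.evaluate import (
    CoverageError,
    ExperimentError,
    LabeledExample,
    UndefinedMetricsError,
    confusion_from_pairs,
    event_sensitivity,
    mean_latency,
)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert (m.acc, m.sens, m.spec, m.pre, m.f1, m.macc) == (100,) * 6

    def test_near_perfect_counts(self):
        # 49/0/51/2: accuracy 100/102, sensitivity 49/51, F1 49/50
        m = compute_metrics(ConfusionCounts(tp=49, fp=0, tn=51, fn=2))
        assert m.acc == 98.04
        assert m.sens == 96.08
        assert m.spec == 100.0
        assert m.pre == 100.0
        assert m.f1 == 98.0
        assert m.macc == 98.04

    def test_degenerate_all_negative_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=10))
        assert m.sens == 0.0
        assert m.spec == 100.0
        assert m.macc == 50.0
        assert m.pre is None  # 0/0 flagged undefined, not NaN

    def test_all_zero_counts_rejected(self):
        with pytest.raises(UndefinedMetricsError):
            compute_metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_matches_sklearn_confusion_matrix(self, rng):
        truth = rng.choice(["seizure", "interictal"], size=200)
        pred = np.where(
            rng.random(200) < 0.8, truth, rng.choice(["seizure", "interictal"], 200)
        )
        counts = confusion_from_pairs(truth, pred)
        tn, fp, fn, tp = confusion_matrix(
            truth, pred, labels=["interictal", "seizure"]
        ).ravel()
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
        m = compute_metrics(counts)
        assert m.acc == pytest.approx(100 * (tp + tn) / 200, abs=0.01)

    def test_balanced_test_set_acc_equals_macc(self, rng):
        for _ in range(20):
            tp = int(rng.integers(0, 50))
            fp = int(rng.integers(0, 50))
            fn, tn = 50 - tp, 50 - fp  # TP+FN = TN+FP = 50
            m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert m.acc == m.macc


class TestEventDetection:
    def test_delayed_detection_latency(self):
        """Onset 3527 s with the first positive window at 3575 s: 48 s."""
        times = np.arange(3527.0, 3641.0, 2.0)
        predicted = ["seizure" if t >= 3575.0 else "interictal" for t in times]
        results = event_detection(times, predicted, [(3527.0, 3643.0)])
        assert results[0].detected
        assert results[0].latency_s == 48.0

    def test_immediate_detection(self):
        times = [10.0, 12.0, 14.0]
        results = event_detection(times, ["seizure"] * 3, [(10.0, 16.0)])
        assert results[0].latency_s == 0.0

    def test_missed_event(self):
        results = event_detection(
            [10.0, 12.0], ["interictal", "interictal"], [(10.0, 14.0)]
        )
        assert not results[0].detected
        assert results[0].latency_s is None

    def test_uncovered_event_raises(self):
        with pytest.raises(CoverageError):
            event_detection([100.0], ["seizure"], [(10.0, 14.0)])

    def test_sensitivity_and_mean_latency_aggregation(self):
        times = [0.0, 2.0, 20.0, 22.0]
        predicted = ["interictal", "seizure", "seizure", "seizure"]
        results = event_detection(times, predicted, [(0.0, 4.0), (20.0, 24.0)])
        assert event_sensitivity(results) == 100.0
        assert mean_latency(results) == 1.0  # (2 + 0) / 2


def trivial_examples(rng, n_per_class, n_events=4, size=32):
    """Separable 32x32 images wired to segment metadata: seizure windows
    tile ``n_events`` 10-s events; interictal windows live elsewhere."""
    examples, annotations = [], []
    per_event = n_per_class // n_events
    t = 0.0
    for ev in range(n_events):
        onset = 100.0 * (ev + 1)
        annotations.append((onset, onset + 2.0 * per_event))
        for k in range(per_event):
            img = np.full((size, size, 3), 255, np.uint8)
            img[4:28, : 16 + int(rng.integers(0, 8))] = (220, 30, 30)
            examples.append(
                LabeledExample(img, "seizure", onset + 2.0 * k, ev)
            )
    for k in range(n_per_class):
        img = np.full((size, size, 3), 255, np.uint8)
        img[4:28, : 2 + int(rng.integers(0, 3))] = (220, 30, 30)
        examples.append(LabeledExample(img, "interictal", 500.0 + 2.0 * k, None))
        t += 2.0
    return examples, annotations


class TestExperiment1:
    def test_split_proportions_and_determinism(self, rng):
        examples, _ = trivial_examples(rng, 40)
        cfg = ClassifierConfig(epochs=4, batch_size=16, seed=0)
        m1, c1 = run_experiment1(examples, cfg, test_fraction=0.3, seed=5)
        assert c1.total == round(0.3 * len(examples))
        assert c1.tp + c1.fn == c1.tn + c1.fp  # stratified: balanced test set
        m2, c2 = run_experiment1(examples, cfg, test_fraction=0.3, seed=5)
        assert m1 == m2 and c1 == c2

    def test_separable_examples_classified_accurately(self, rng):
        examples, _ = trivial_examples(rng, 40)
        m, _ = run_experiment1(
            examples, ClassifierConfig(epochs=5, batch_size=16, seed=1), seed=1
        )
        assert m.acc >= 95.0

    def test_single_class_rejected(self, rng):
        examples, _ = trivial_examples(rng, 10)
        seiz_only = [e for e in examples if e.label == "seizure"]
        with pytest.raises(ExperimentError):
            run_experiment1(seiz_only, ClassifierConfig(epochs=1))


class TestExperiment2:
    def test_one_model_per_event_and_no_leakage(self, rng, monkeypatch):
        examples, annotations = trivial_examples(rng, 24, n_events=4)
        calls = []
        import topoeeg.classify as classify_mod

        original = classify_mod.train

        def counting_train(images, labels, config=None):
            calls.append(len(images))
            return original(images, labels, config)

        monkeypatch.setattr("topoeeg.evaluate.classify.train", counting_train)
        results, sens, lat = run_experiment2(
            examples, annotations, ClassifierConfig(epochs=3, batch_size=16, seed=0),
            seed=0,
        )
        assert len(calls) == 4  # exactly S trained models
        assert len(results) == 4

    def test_separable_events_all_detected_immediately(self, rng):
        examples, annotations = trivial_examples(rng, 24, n_events=4)
        results, sens, lat = run_experiment2(
            examples, annotations, ClassifierConfig(epochs=4, batch_size=16, seed=1),
            seed=1,
        )
        assert sens == 100.0
        assert lat == 0.0

    def test_fewer_than_two_events_rejected(self, rng):
        examples, annotations = trivial_examples(rng, 12, n_events=1)
        with pytest.raises(ExperimentError):
            run_experiment2(examples, annotations, ClassifierConfig(epochs=1))
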