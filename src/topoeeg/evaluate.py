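"""Segment-based metrics, event-based detection latency, experiment drivers.

Segment metrics follow the usual confusion-matrix definitions on 2-s
windows, reported as percentages:

    Acc  = (TP+TN)/(TP+FP+TN+FN) * 100
    Sens = TP/(TP+FN) * 100          Spec = TN/(TN+FP) * 100
    Pre  = TP/(TP+FP) * 100          F1   = TP/(TP+0.5(FP+FN)) * 100
    mAcc = (Sens+Spec)/2

Event-based evaluation asks, per annotated seizure event, whether any test
window inside it was called seizure; the *detection latency* is the start
time of the earliest such window minus the annotated onset.  Experiment 1
is a stratified 70/30 split on segments; Experiment 2 is
leave-one-seizure-event-out with matched held-out interictal windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import classify
from .recording import Annotation

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EventResult",
    "LabeledExample",
    "compute_metrics",
    "confusion_from_pairs",
    "event_detection",
    "run_experiment1",
    "run_experiment2",
]


class UndefinedMetricsError(ValueError):
    """All confusion counts are zero; no metric is defined."""


class CoverageError(ValueError):
    """A seizure event has no test segments."""


class ExperimentError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Percent metrics rounded to 2 decimals; ``None`` marks an undefined
    value (zero denominator), which is never propagated as NaN."""

    acc: Optional[float]
    sens: Optional[float]
    spec: Optional[float]
    pre: Optional[float]
    f1: Optional[float]
    macc: Optional[float]


@dataclass(frozen=True)
class EventResult:
    event_index: int
    detected: bool
    latency_s: Optional[float]

    def __post_init__(self) -> None:
        if self.detected != (self.latency_s is not None):
            raise ValueError("latency must be present exactly when detected")


@dataclass
class LabeledExample:
    """A rendered barcode image together with its segment metadata."""

    image: object  # BarcodeImage
    label: str
    start_time: float
    event_index: Optional[int] = None
    subject_id: str = "synthetic"


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """All six segment metrics from confusion counts, to 2 decimals."""
    if counts.total == 0:
        raise UndefinedMetricsError("all confusion counts are zero")
    acc = _ratio(counts.tp + counts.tn, counts.total)
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    pre = _ratio(counts.tp, counts.tp + counts.fp)
    f1 = _ratio(counts.tp, counts.tp + 0.5 * (counts.fp + counts.fn))
    macc = None if sens is None or spec is None else (sens + spec) / 2
    rnd = lambda v: None if v is None else round(v, 2)
    return Metrics(rnd(acc), rnd(sens), rnd(spec), rnd(pre), rnd(f1), rnd(macc))


def confusion_from_pairs(
    true_labels: Sequence[str], predicted: Sequence[str], positive: str = "seizure"
) -> ConfusionCounts:
    t = np.asarray(true_labels) == positive
    p = np.asarray(predicted) == positive
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def event_detection(
    segment_times: Sequence[float],
    predicted: Sequence[str],
    annotations: Sequence[Annotation],
    window_seconds: float = 2.0,
) -> list[EventResult]:
    """Per-event detection and latency from time-ordered test predictions.

    A window belongs to an event when fully inside its annotated interval.
    Latency is ``earliest positive window start - onset`` (0 when the first
    in-event window is already positive).
    """
    times = np.asarray(segment_times, dtype=float)
    if np.any(np.diff(times) < 0):
        order = np.argsort(times, kind="stable")
        times = times[order]
        predicted = [predicted[i] for i in order]
    results = []
    for ev, (onset, offset) in enumerate(annotations):
        inside = [
            i
            for i, t in enumerate(times)
            if t >= onset - 1e-9 and t + window_seconds <= offset + 1e-9
        ]
        if not inside:
            raise CoverageError(f"event {ev} [{onset}, {offset}) has no test segments")
        positive = [i for i in inside if predicted[i] == "seizure"]
        if positive:
            latency = float(times[positive[0]] - onset)
            results.append(EventResult(ev, True, round(latency, 2)))
        else:
            results.append(EventResult(ev, False, None))
    return results


def event_sensitivity(results: Sequence[EventResult]) -> float:
    return 100.0 * sum(r.detected for r in results) / len(results)


def mean_latency(results: Sequence[EventResult]) -> Optional[float]:
    lats = [r.latency_s for r in results if r.detected]
    return None if not lats else round(float(np.mean(lats)), 2)


def run_experiment1(
    examples: Sequence[LabeledExample],
    config: Optional[classify.ClassifierConfig] = None,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[Metrics, ConfusionCounts]:
    """Stratified segment-level split, train, evaluate on the held-out part."""
    labels = [ex.label for ex in examples]
    if len(set(labels)) < 2:
        raise ExperimentError("need both classes for a stratified split")
    idx = np.arange(len(examples))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    model = classify.train(
        [examples[i].image for i in train_idx],
        [examples[i].label for i in train_idx],
        config,
    )
    predicted, _ = classify.predict(model, [examples[i].image for i in test_idx])
    counts = confusion_from_pairs([examples[i].label for i in test_idx], predicted)
    return compute_metrics(counts), counts


def run_experiment2(
    examples: Sequence[LabeledExample],
    annotations: Sequence[Annotation],
    config: Optional[classify.ClassifierConfig] = None,
    seed: int = 0,
    window_seconds: float = 2.0,
) -> tuple[list[EventResult], float, Optional[float]]:
    """Leave-one-seizure-event-out loop.

    For each of the S events: train on the other S-1 events' seizure
    windows plus the interictal windows not reserved for this fold, test on
    the held-out event's windows plus its reserved matched interictal
    windows.  Interictal windows are partitioned across folds round-robin
    (seeded order) so test folds keep both classes without leakage.
    Returns per-event results, event sensitivity (%), and mean latency (s).
    """
    events = sorted({ex.event_index for ex in examples if ex.event_index is not None})
    if len(events) < 2:
        raise ExperimentError(f"leave-one-event-out requires >= 2 events, got {len(events)}")
    if len(events) != len(annotations):
        raise ExperimentError(
            f"{len(events)} events in segments but {len(annotations)} annotations"
        )
    inter_idx = [i for i, ex in enumerate(examples) if ex.label == "interictal"]
    rng = np.random.default_rng(seed)
    inter_perm = rng.permutation(len(inter_idx))
    fold_of_inter = {
        inter_idx[p]: f % len(events) for f, p in enumerate(inter_perm)
    }

    results: list[EventResult] = []
    for fold, ev in enumerate(events):
        test_ids = [
            i
            for i, ex in enumerate(examples)
            if (ex.event_index == ev)
            or (ex.label == "interictal" and fold_of_inter[i] == fold)
        ]
        train_ids = [i for i in range(len(examples)) if i not in set(test_ids)]
        held_out = {i for i in train_ids if examples[i].event_index == ev}
        assert not held_out, "held-out event leaked into training fold"
        model = classify.train(
            [examples[i].image for i in train_ids],
            [examples[i].label for i in train_ids],
            config,
        )
        predicted, _ = classify.predict(model, [examples[i].image for i in test_ids])
        ev_times = [examples[i].start_time for i in test_ids]
        ev_result = event_detection(
            ev_times, predicted, [annotations[ev]], window_seconds
        )[0]
        results.append(EventResult(ev, ev_result.detected, ev_result.latency_s))
    return results, event_sensitivity(results), mean_latency(results)
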