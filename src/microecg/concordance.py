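"""FDA-label concordance: confusion matrices and classification metrics.

Two endpoints are scored against the label ground truth: QT prolongation
(predicted positive when the Fridericia-corrected FPD percent change crosses
the MID threshold in the prolongation direction) and TdP/arrhythmia
(predicted positive when irregular events were detected at any dose).  The
vehicle is counted in the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dose import DIR_UP, CompoundCall
from .errors import InputError

ENDPOINT_QT = "QT_prolongation"
ENDPOINT_TDP = "TdP_arrhythmia"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity / specificity / accuracy in percent (None when undefined)."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def rounded(self, ndigits: int = 1) -> tuple:
        return tuple(None if v is None else round(v, ndigits)
                     for v in (self.sensitivity, self.specificity, self.accuracy))


def classify_qt(calls: dict[str, CompoundCall],
                threshold: str = "MID") -> dict[str, bool]:
    """Predicted QT-prolongation label: crossing at the threshold, upward."""
    return {name: call.at(threshold).direction == DIR_UP
            for name, call in calls.items()}


def classify_arrhythmia(calls: dict[str, CompoundCall]) -> dict[str, bool]:
    """Predicted TdP label: any arrhythmic event detected along the ladder."""
    return {name: call.arrhythmia for name, call in calls.items()}


def build_confusion(predicted: dict[str, bool], labels: pd.DataFrame,
                    endpoint: str) -> ConfusionMatrix:
    """2x2 counting of predictions against FDA-label ground truth.

    ``labels`` is indexed by compound with boolean ``qt_label`` and
    ``tdp_label`` columns.
    """
    col = {ENDPOINT_QT: "qt_label", ENDPOINT_TDP: "tdp_label"}.get(endpoint)
    if col is None:
        raise InputError(f"unknown endpoint {endpoint!r}")
    tp = tn = fp = fn = 0
    for compound, pred in predicted.items():
        if compound not in labels.index:
            raise InputError(f"no FDA label for compound {compound!r}")
        truth = bool(labels.loc[compound, col])
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total.

    An empty truth class leaves the corresponding metric undefined (None),
    never silently zero.
    """
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else None
    acc = 100.0 * (cm.tp + cm.tn) / cm.total if cm.total else None
    return MetricSet(sensitivity=sens, specificity=spec, accuracy=acc)


def roc_over_thresholds(calls_by_threshold: dict[str, dict[str, CompoundCall]],
                        labels: pd.DataFrame,
                        endpoint: str = ENDPOINT_QT) -> pd.DataFrame:
    """Metric triples across the threshold grid (INF...SUP where available).

    Raising the threshold can only shrink the predicted-positive set, so the
    sweep traces the ROC of the screen.
    """
    rows = []
    for name, calls in calls_by_threshold.items():
        predicted = (classify_qt(calls, threshold=name)
                     if endpoint == ENDPOINT_QT else classify_arrhythmia(calls))
        cm = build_confusion(predicted, labels, endpoint)
        m = compute_metrics(cm)
        rows.append({"threshold": name, "n_positive_predictions": cm.tp + cm.fp,
                     "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
                     "sensitivity": m.sensitivity, "specificity": m.specificity,
                     "accuracy": m.accuracy})
    return pd.DataFrame(rows)
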