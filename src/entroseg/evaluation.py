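"""Segmentation quality metrics against ground truth.

Thresholding yields classes already ordered by gray level, but evaluation
must survive arbitrary relabeling of the prediction, so predicted classes are
first matched to truth classes by greedy majority overlap (largest confusion
entry first; ties toward lower class indices).  Per matched class the report
carries Dice ``2|A∩B| / (|A|+|B|)`` and Jaccard ``|A∩B| / |A∪B|`` — related
by ``dice = 2J/(1+J)`` — plus overall pixel accuracy, the full confusion
table, and per-cut absolute threshold error when reference cuts are given.
Truth classes left unmatched (e.g. absent from the prediction) score Dice 0
and are flagged rather than dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import DomainError, LabelMap, ThresholdVector

__all__ = ["EvalReport", "evaluate", "match_classes"]


@dataclass(frozen=True)
class EvalReport:
    per_class_dice: tuple[float, ...]
    per_class_jaccard: tuple[float, ...]
    overall_accuracy: float
    confusion: np.ndarray  # rows: truth classes, cols: predicted classes
    matching: tuple[int, ...]  # matching[t] = predicted class matched to truth t (-1 if none)
    unmatched_truth: tuple[int, ...]
    threshold_error: tuple[int, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "per_class_dice": list(self.per_class_dice),
            "per_class_jaccard": list(self.per_class_jaccard),
            "overall_accuracy": self.overall_accuracy,
            "confusion": self.confusion.tolist(),
            "matching": list(self.matching),
            "unmatched_truth": list(self.unmatched_truth),
            "threshold_error": (
                None if self.threshold_error is None else list(self.threshold_error)
            ),
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv_row(self) -> dict:
        """Flat scalar row for batch sweeps."""
        row = {"overall_accuracy": self.overall_accuracy}
        for i, (d, j) in enumerate(zip(self.per_class_dice, self.per_class_jaccard)):
            row[f"dice_{i}"] = d
            row[f"jaccard_{i}"] = j
        if self.threshold_error is not None:
            for i, e in enumerate(self.threshold_error):
                row[f"cut_error_{i + 1}"] = e
        return row


def match_classes(confusion: np.ndarray) -> np.ndarray:
    """Greedy majority-overlap assignment of predicted to truth classes.

    Pairs are taken in decreasing overlap, ties broken by lower truth then
    lower predicted index; each class is used at most once.  Returns
    ``match[t] = p`` (or ``-1`` when truth class ``t`` gets no partner).
    Invariant to any renumbering of the prediction labels.
    """
    n_t, n_p = confusion.shape
    order = sorted(
        ((int(confusion[t, p]), t, p) for t in range(n_t) for p in range(n_p)),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    match = np.full(n_t, -1, dtype=np.int64)
    used_p: set[int] = set()
    for overlap, t, p in order:
        if overlap <= 0:
            break
        if match[t] == -1 and p not in used_p:
            match[t] = p
            used_p.add(p)
    return match


def evaluate(
    pred: LabelMap,
    truth: LabelMap,
    reference_cuts: ThresholdVector | None = None,
    predicted_cuts: ThresholdVector | None = None,
) -> EvalReport:
    """Score a predicted label map against the ground truth.

    ``reference_cuts``/``predicted_cuts`` are optional; when both are present
    the report also carries per-cut absolute gray-level errors.
    """
    if pred.shape != truth.shape:
        raise DomainError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    n_t, n_p = truth.n_classes, pred.n_classes
    flat_t = truth.labels.ravel().astype(np.int64)
    flat_p = pred.labels.ravel().astype(np.int64)
    confusion = np.bincount(flat_t * n_p + flat_p, minlength=n_t * n_p).reshape(n_t, n_p)

    match = match_classes(confusion)
    truth_counts = confusion.sum(axis=1)
    pred_counts = confusion.sum(axis=0)

    dice = np.zeros(n_t)
    jacc = np.zeros(n_t)
    correct = 0
    for t in range(n_t):
        p = match[t]
        if p < 0:
            continue
        inter = confusion[t, p]
        union = truth_counts[t] + pred_counts[p] - inter
        denom = truth_counts[t] + pred_counts[p]
        dice[t] = 2.0 * inter / denom if denom else 0.0
        jacc[t] = inter / union if union else 0.0
        correct += inter
    accuracy = correct / flat_t.size

    unmatched = tuple(int(t) for t in np.flatnonzero(match < 0))
    threshold_error = None
    if reference_cuts is not None and predicted_cuts is not None:
        if reference_cuts.m != predicted_cuts.m:
            raise DomainError(
                f"cut-count mismatch: reference m={reference_cuts.m}, "
                f"predicted m={predicted_cuts.m}"
            )
        threshold_error = tuple(
            abs(int(a) - int(b))
            for a, b in zip(predicted_cuts.cuts, reference_cuts.cuts)
        )

    return EvalReport(
        per_class_dice=tuple(float(d) for d in dice),
        per_class_jaccard=tuple(float(j) for j in jacc),
        overall_accuracy=float(accuracy),
        confusion=confusion,
        matching=tuple(int(p) for p in match),
        unmatched_truth=unmatched,
        threshold_error=threshold_error,
    )
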