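"""Macro-F1 evaluation of cell-type predictions.

The score is the unweighted mean over cell types of each type's F1
(harmonic mean of precision and recall), so small cell types weigh as
much as large ones. Cell types are enumerated from the truth labels only:
a label that is only ever predicted contributes false positives to the
true classes but adds no class of its own. Undefined ratios (0/0) are
taken as 0.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

__all__ = ["ClassMetrics", "macro_f1"]


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    cell_type: str
    precision: float
    recall: float
    f1: float
    support: int


def macro_f1(truth: Sequence[str], predicted: Sequence[str]) -> tuple[float, list[ClassMetrics]]:
    """Macro-averaged F1 plus the per-class precision/recall/F1 table."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted labels"
        )
    if not truth:
        raise ValueError("truth labels are empty")
    classes = sorted(set(truth))
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    support = {c: 0 for c in classes}
    for t, p in zip(truth, predicted):
        support[t] += 1
        if t == p:
            tp[t] += 1
        else:
            fn[t] += 1
            if p in fp:
                fp[p] += 1
    metrics = []
    for c in classes:
        prec = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] > 0 else 0.0
        rec = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        metrics.append(ClassMetrics(c, prec, rec, f1, support[c]))
    return sum(m.f1 for m in metrics) / len(classes), metrics
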