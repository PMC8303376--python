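"""Multilabel evaluation: per-tool confusion metrics and exact-match accuracy.

Per tool, frames are tallied into TP/TN/FP/FN and summarised as
precision = TP/(TP+FP), recall = TP/(TP+FN), and the F1 harmonic mean,
reported as percentages at one decimal (half-up).  The frame-level
accuracy is the exact-match (subset) accuracy: a frame counts as correct
only when the predicted label set equals the ground truth exactly, so a
frame with three true tools and four predictions is wrong even though
nine of its ten per-label decisions are right.

Confusion tables can also be expressed as percentages normalised within
the truly-present and truly-absent partitions (TP% + FN% = 100 and
TN% + FP% = 100 row conventions).

Metrics with a zero denominator are reported as not-applicable (None),
never silently as 0 or 100, so they cannot corrupt column averages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .labelspace import ENVIRONMENT, LabelVector, TOOL_NAMES

__all__ = [
    "ConfusionCounts",
    "confusion",
    "precision",
    "recall",
    "f1_from_pr",
    "accuracy",
    "exact_match_accuracy",
    "table4_percentages",
    "column_average",
    "round1",
    "metric_report",
    "report_to_csv",
]


def round1(x: float) -> float:
    """Round half-up to one decimal (the reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-label frame tallies."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _true_set(truth) -> frozenset[str]:
    if isinstance(truth, LabelVector):
        return truth.to_labels()
    if isinstance(truth, (set, frozenset)):
        return frozenset(truth)
    return LabelVector.from_array(truth).to_labels()


def confusion(
    predicted: Sequence[Iterable[str]],
    truth: Sequence,
    label: str,
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for one label over paired frame sequences."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    tp = tn = fp = fn = 0
    for pred, true in zip(predicted, truth):
        p = label in set(pred)
        t = label in _true_set(true)
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def precision(c: ConfusionCounts) -> float | None:
    """100*TP/(TP+FP); None (not applicable) when nothing was predicted positive."""
    if c.tp + c.fp == 0:
        return None
    return 100.0 * c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float | None:
    """100*TP/(TP+FN); None when the label never truly occurs."""
    if c.tp + c.fn == 0:
        return None
    return 100.0 * c.tp / (c.tp + c.fn)


def f1_from_pr(p: float | None, r: float | None) -> float | None:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if p is None or r is None:
        return None
    if p + r == 0:
        return None
    return 2.0 * p * r / (p + r)


def accuracy(c: ConfusionCounts) -> float | None:
    """Per-label accuracy 100*(TP+TN)/total."""
    if c.total == 0:
        return None
    return 100.0 * (c.tp + c.tn) / c.total


def exact_match_accuracy(predicted: Sequence[Iterable[str]], truth: Sequence) -> float:
    """Percentage of frames whose predicted set equals the truth exactly.

    The comparison covers the full label vector, Environment included.
    """
    if len(predicted) != len(truth):
        raise ValueError("length mismatch between predictions and truth")
    if not predicted:
        raise ValueError("exact-match accuracy is undefined on empty input")
    hits = sum(
        frozenset(pred) == _true_set(true) for pred, true in zip(predicted, truth)
    )
    return 100.0 * hits / len(predicted)


def table4_percentages(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(TP%, TN%, FP%, FN%) normalised within present/absent partitions.

    TP% = 100*TP/(TP+FN) and FN% = 100*FN/(TP+FN) over truly-present
    frames; TN% = 100*TN/(TN+FP) and FP% = 100*FP/(TN+FP) over
    truly-absent frames — so TP% + FN% = 100 and TN% + FP% = 100.
    """
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0 or neg == 0:
        raise ValueError("percentages need at least one positive and one negative frame")
    return (
        100.0 * c.tp / pos,
        100.0 * c.tn / neg,
        100.0 * c.fp / neg,
        100.0 * c.fn / pos,
    )


def column_average(values: Sequence[float]) -> float:
    """Arithmetic mean of a metric column, reported at one decimal."""
    if len(values) == 0:
        raise ValueError("cannot average an empty column")
    return round1(float(np.mean(values)))


def metric_report(
    predicted: Sequence[Iterable[str]],
    truth: Sequence,
    tools: Sequence[str] | None = None,
) -> dict:
    """Per-tool precision/recall/F1/accuracy table plus exact-match accuracy.

    Environment is excluded from the per-tool rows (it is background, not
    a tool) but participates in the exact-match frame comparison.  Values
    are rounded to one decimal; not-applicable cells are None and are
    left out of the averages.
    """
    if tools is None:
        tools = [t for t in TOOL_NAMES if t != ENVIRONMENT]
    rows: dict[str, dict] = {}
    for tool in tools:
        c = confusion(predicted, truth, tool)
        p, r = precision(c), recall(c)
        rows[tool] = {
            "precision": None if p is None else round1(p),
            "recall": None if r is None else round1(r),
            "f1": None if f1_from_pr(p, r) is None else round1(f1_from_pr(p, r)),
            "accuracy": None if accuracy(c) is None else round1(accuracy(c)),
            "counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
        }
    averages = {}
    for key in ("precision", "recall", "f1", "accuracy"):
        col = [rows[t][key] for t in tools if rows[t][key] is not None]
        averages[key] = column_average(col) if col else None
    return {
        "per_tool": rows,
        "average": averages,
        "exact_match_accuracy": round1(exact_match_accuracy(predicted, truth)),
        "n_frames": len(predicted),
    }


def report_to_csv(report: dict, path: str | Path) -> None:
    """Write a metric report as a tool-rows CSV with an Average row."""
    lines = ["tool,precision,recall,f1,accuracy"]

    def fmt(v):
        return "NA" if v is None else f"{v:.1f}"

    for tool, row in report["per_tool"].items():
        lines.append(
            f"{tool},{fmt(row['precision'])},{fmt(row['recall'])},"
            f"{fmt(row['f1'])},{fmt(row['accuracy'])}"
        )
    avg = report["average"]
    lines.append(
        f"Average,{fmt(avg['precision'])},{fmt(avg['recall'])},"
        f"{fmt(avg['f1'])},{fmt(avg['accuracy'])}"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
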