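"""Workflow phase estimation from per-frame tool detections.

For each phase, a binary temporal signal marks the frames whose detected
tool set (Environment ignored) equals the phase's right-phase tool set.
The signal is smoothed with a centred moving-average filter and
re-binarised; maximal runs of 1s ("batches") are candidate occurrences.
Phases are matched sequentially: each phase claims its first batch that
extends beyond the previously accepted batch (allowing half a window of
smoothing blur at the start) — earlier hits are discarded, since a
phase cannot begin before the previous one ended.  The limit between
two consecutively detected phases is the
rounded mean of the previous phase's batch end and the next phase's
batch start; the boundary frame is assigned to the earlier phase.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .detector import DetectionLog
from .labelspace import ENVIRONMENT, PHASES, PhaseSpec, Timeline

__all__ = [
    "PhaseEstimationConfig",
    "PhaseEstimate",
    "build_phase_signal",
    "smooth_and_binarize",
    "find_batches",
    "estimate_phases",
    "phase_coverage",
    "coverage_report",
    "write_report",
]


@dataclass(frozen=True)
class PhaseEstimationConfig:
    """Parameters of the temporal post-processing.

    window: moving-average length in frames (odd; 15 is one second at the
        15 fps recording rate and is the single most consequential free
        parameter).
    threshold: binarisation level applied to the smoothed signal.
    relaxed_match: when True a frame counts as right-phase if the phase
        tools are a subset of the detections and no wrong-phase tool is
        required to be absent only among known tools; the default exact
        rule requires set equality (Environment ignored).
    """

    window: int = 15
    threshold: float = 0.5
    relaxed_match: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class PhaseEstimate:
    """Outcome of sequential matching for one phase."""

    phase: str
    detected: bool
    raw_batch: tuple[int, int] | None = None
    final_interval: tuple[int, int] | None = None


def build_phase_signal(
    log: DetectionLog, phase: PhaseSpec | str, relaxed: bool = False
) -> np.ndarray:
    """Binary vector: 1 where the frame's detections match the phase tools.

    The Environment label is ignored.  Under the exact rule (default) the
    detected set must equal the right-phase set; any wrong-phase tool, or
    a missing right-phase tool, gives 0.  An empty detection ("None")
    never matches.  The relaxed rule only requires the right-phase tools
    to be present.
    """
    from .labelspace import phase_tools

    tools = phase.tools if isinstance(phase, PhaseSpec) else phase_tools(phase)
    signal = np.zeros(len(log.records), dtype=np.int8)
    for i, rec in enumerate(log.records):
        detected = rec.detected - {ENVIRONMENT}
        ok = tools <= detected if relaxed else detected == tools
        signal[i] = 1 if ok else 0
    return signal


def smooth_and_binarize(
    signal: np.ndarray, cfg: PhaseEstimationConfig | None = None
) -> np.ndarray:
    """Centred moving average (window shrinking at the edges), then threshold.

    Element ``t`` of the smoothed signal is the mean of the frames within
    ``window // 2`` of ``t`` that exist; the output is 1 where that mean
    is strictly above the threshold.
    """
    cfg = cfg or PhaseEstimationConfig()
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if cfg.window > n:
        raise ValueError(f"window {cfg.window} exceeds signal length {n}")
    half = cfg.window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    means = (csum[hi] - csum[lo]) / (hi - lo)
    return (means > cfg.threshold).astype(np.int8)


def find_batches(binary: Sequence[int] | np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as inclusive (start, end) pairs, in order.

    Implemented with a difference vector over the padded signal: +1 marks
    a batch start, -1 the frame after its end.
    """
    arr = np.asarray(binary)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("find_batches expects a binary vector")
    padded = np.concatenate([[0], arr.astype(np.int8), [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_phases(
    log: DetectionLog,
    phases: Sequence[PhaseSpec] = PHASES,
    cfg: PhaseEstimationConfig | None = None,
) -> list[PhaseEstimate]:
    """Sequentially match each phase to its first admissible batch of 1s.

    For each phase in order, the first batch that reaches past the end of
    the previously accepted batch — and starts no earlier than half a
    window before it, tolerating smoothing blur — is accepted, and the
    cursor advances to its end.  Earlier batches are discarded.  An
    undetected phase is flagged and leaves the cursor unchanged.  Final
    intervals replace the boundary between consecutively detected phases
    by the rounded mean of the earlier batch's end and the later batch's
    start (boundary frame assigned to the earlier phase); the first
    detected phase keeps its batch start and the last its batch end.
    """
    cfg = cfg or PhaseEstimationConfig()
    estimates: list[PhaseEstimate] = []
    # Smoothing blurs each batch edge by up to half a window, so two
    # consecutive phases' batches routinely overlap by a few frames.  A
    # batch is admissible if it extends beyond the previous batch and
    # starts no more than half a window before its end.
    tol = cfg.window // 2
    cursor = -1  # end of the previously accepted batch
    for phase in phases:
        signal = build_phase_signal(log, phase, relaxed=cfg.relaxed_match)
        batches = find_batches(smooth_and_binarize(signal, cfg))
        chosen = next(
            (b for b in batches if b[0] >= cursor + 1 - tol and b[1] > cursor), None
        )
        if chosen is None:
            estimates.append(PhaseEstimate(phase.id, detected=False))
        else:
            estimates.append(PhaseEstimate(phase.id, detected=True, raw_batch=chosen))
            cursor = chosen[1]

    detected = [e for e in estimates if e.detected]
    for est in detected:
        est.final_interval = est.raw_batch
    for prev, nxt in zip(detected, detected[1:]):
        boundary = _round_half_up((prev.raw_batch[1] + nxt.raw_batch[0]) / 2.0)
        boundary = max(boundary, prev.final_interval[0])
        prev.final_interval = (prev.final_interval[0], boundary)
        nxt.final_interval = (boundary + 1, max(nxt.raw_batch[1], boundary + 1))
    return estimates


def phase_coverage(
    ground_truth: tuple[int, int], predicted: tuple[int, int] | None
) -> float:
    """Percentage of the ground-truth interval covered by the prediction.

    Inclusive frame counting; a prediction that starts before and ends
    after the truth scores 100.  An undetected phase (``None``) scores 0.
    """
    gs, ge = ground_truth
    if gs > ge:
        raise ValueError(f"inverted ground-truth interval {ground_truth}")
    if predicted is None:
        return 0.0
    ps, pe = predicted
    if ps > pe:
        raise ValueError(f"inverted predicted interval {predicted}")
    overlap = min(ge, pe) - max(gs, ps) + 1
    if overlap <= 0:
        return 0.0
    return min(100.0, 100.0 * overlap / (ge - gs + 1))


def coverage_report(
    estimates: Sequence[PhaseEstimate], truth: Timeline
) -> list[dict]:
    """Per-phase coverage rows plus interval details."""
    rows = []
    for est in estimates:
        gt = truth.interval(est.phase)
        rows.append(
            {
                "phase": est.phase,
                "ground_truth": list(gt),
                "raw_batch": list(est.raw_batch) if est.raw_batch else None,
                "final_interval": list(est.final_interval) if est.final_interval else None,
                "detected": est.detected,
                "coverage_pct": round(phase_coverage(gt, est.final_interval), 1),
            }
        )
    return rows


def write_report(
    estimates: Sequence[PhaseEstimate],
    path: str | Path,
    truth: Timeline | None = None,
) -> None:
    """Write the estimation report as JSON; with truth, also a coverage CSV."""
    path = Path(path)
    payload = [
        {
            "phase": e.phase,
            "raw_batch": list(e.raw_batch) if e.raw_batch else None,
            "final_interval": list(e.final_interval) if e.final_interval else None,
            "detected": e.detected,
        }
        for e in estimates
    ]
    path.write_text(json.dumps(payload, indent=2))
    if truth is not None:
        rows = coverage_report(estimates, truth)
        with open(path.with_suffix(".coverage.csv"), "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "phase", "ground_truth", "raw_batch", "final_interval",
                    "detected", "coverage_pct",
                ],
            )
            writer.writeheader()
            writer.writerows(rows)
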