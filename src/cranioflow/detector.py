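"""Per-frame multilabel inference, detection thresholding, and CSV logs.

A trained model scores every frame of a video with one confidence per
label in [0, 1].  A tool counts as *detected* when its confidence is
strictly above the threshold (default 0.5); a frame where nothing crosses
the threshold is logged as ``None``.  The time-ordered records form a
:class:`DetectionLog`, serialised to CSV for downstream phase estimation.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .labelspace import LABEL_INDEX, N_LABELS, TOOL_NAMES

__all__ = [
    "DetectionRecord",
    "DetectionLog",
    "threshold_detections",
    "run_inference",
    "write_log",
    "read_log",
]

CSV_HEADER = ["frame", "time_s"] + [f"p_{name}" for name in TOOL_NAMES] + ["detected"]


def threshold_detections(
    probabilities: Sequence[float] | np.ndarray, threshold: float = 0.5
) -> frozenset[str]:
    """Labels whose confidence is strictly above ``threshold``.

    An empty result means no tool was detected ("None" in the log).
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape != (N_LABELS,):
        raise ValueError(f"expected {N_LABELS} probabilities, got shape {probs.shape}")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return frozenset(TOOL_NAMES[i] for i in np.nonzero(probs > threshold)[0])


@dataclass(frozen=True)
class DetectionRecord:
    """One frame's confidences and thresholded tool set."""

    frame: int
    time_s: float
    probabilities: tuple[float, ...]
    detected: frozenset[str]

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")
        if len(self.probabilities) != N_LABELS:
            raise ValueError("record needs one probability per label")


@dataclass
class DetectionLog:
    """Time-ordered per-frame detection records."""

    records: list[DetectionRecord] = field(default_factory=list)
    frame_rate: float = 15.0
    threshold: float = 0.5
    skipped: int = 0

    def __post_init__(self) -> None:
        frames = [r.frame for r in self.records]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.records)

    def detected_sets(self) -> list[frozenset[str]]:
        return [r.detected for r in self.records]


def _as_batch(frames: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([np.asarray(f, dtype=np.float32) for f in frames])


def run_inference(
    model,
    frames: Iterable,
    frame_rate: float = 15.0,
    threshold: float = 0.5,
    batch_size: int = 64,
) -> DetectionLog:
    """Score every frame with ``model`` and build a :class:`DetectionLog`.

    ``frames`` may contain image arrays or file paths; each is run through
    :func:`cranioflow.dataset.preprocess`.  Unreadable frames are skipped
    with a warning and counted in ``log.skipped``.
    """
    from .dataset import load_image, preprocess

    predict = getattr(model, "predict", model)
    records: list[DetectionRecord] = []
    skipped = 0
    batch: list[np.ndarray] = []
    batch_idx: list[int] = []

    def flush() -> None:
        if not batch:
            return
        probs = np.asarray(predict(_as_batch(batch)), dtype=float)
        probs = np.clip(probs, 0.0, 1.0)
        for idx, p in zip(batch_idx, probs):
            records.append(
                DetectionRecord(
                    frame=idx,
                    time_s=idx / frame_rate,
                    probabilities=tuple(float(v) for v in p),
                    detected=threshold_detections(p, threshold),
                )
            )
        batch.clear()
        batch_idx.clear()

    for i, frame in enumerate(frames):
        try:
            if isinstance(frame, (str, Path)):
                frame = load_image(frame)
            batch.append(preprocess(frame))
            batch_idx.append(i)
        except Exception as exc:  # unreadable frame: skip, keep going
            warnings.warn(f"skipping unreadable frame {i}: {exc}")
            skipped += 1
            continue
        if len(batch) >= batch_size:
            flush()
    flush()
    return DetectionLog(records, frame_rate=frame_rate, threshold=threshold, skipped=skipped)


def _format_detected(detected: frozenset[str]) -> str:
    if not detected:
        return "None"
    return ";".join(sorted(detected, key=LABEL_INDEX.__getitem__))


def _parse_detected(text: str) -> frozenset[str]:
    if text == "None":
        return frozenset()
    return frozenset(text.split(";"))


def write_log(log: DetectionLog, path: str | Path) -> None:
    """Write a detection log as CSV (probabilities at 6 decimals)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in log.records:
            writer.writerow(
                [rec.frame, f"{rec.time_s:.6f}"]
                + [f"{p:.6f}" for p in rec.probabilities]
                + [_format_detected(rec.detected)]
            )


def read_log(
    path: str | Path, frame_rate: float = 15.0, threshold: float = 0.5
) -> DetectionLog:
    """Read a detection-log CSV written by :func:`write_log`."""
    records: list[DetectionRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty detection log") from None
        if header != CSV_HEADER:
            raise ValueError(f"{path}:1: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(CSV_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(CSV_HEADER)} fields")
            try:
                frame = int(row[0])
                time_s = float(row[1])
                probs = tuple(float(v) for v in row[2 : 2 + N_LABELS])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(
                DetectionRecord(frame, time_s, probs, _parse_detected(row[-1]))
            )
    return DetectionLog(records, frame_rate=frame_rate, threshold=threshold)
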