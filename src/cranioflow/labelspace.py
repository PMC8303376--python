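"""Tool vocabulary, surgical phase taxonomy, and label encodings.

The workflow of an open cranial vault remodeling intervention is described
by eleven ordered phases (P1..P11), each characterised by the set of
surgical tools present in the field ("right-phase tools").  Frames are
annotated with a multilabel one-hot vector over nine tools plus an
``Environment`` label that marks background content (phantom, empty
gloved hands).  ``Environment`` is a label in the classification problem
but never a member of any phase tool set.

The canonical label order is alphabetical with ``Environment`` last; this
fixed ordering makes one-hot vectors and CSV columns reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TOOL_NAMES",
    "ENVIRONMENT",
    "N_LABELS",
    "LabelingError",
    "LabelVector",
    "PhaseSpec",
    "PHASES",
    "Timeline",
    "phase_tools",
    "encode_folder_name",
    "folder_name_for",
    "phases_to_json",
    "phases_from_json",
]

#: Canonical label ordering: the nine tools alphabetically, Environment last.
TOOL_NAMES: tuple[str, ...] = (
    "Forceps",
    "FTGuide",
    "Handpiece",
    "Motor",
    "Osteotome",
    "Pointer",
    "Scalpel",
    "Scissors",
    "SOGuide",
    "Environment",
)

ENVIRONMENT = "Environment"
N_LABELS = len(TOOL_NAMES)

LABEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(TOOL_NAMES)}

# Case-insensitive lookup plus aliases for the prose spellings with spaces.
_CANONICAL: dict[str, str] = {name.lower(): name for name in TOOL_NAMES}
_CANONICAL.update(
    {
        "so guide": "SOGuide",
        "so_guide": "SOGuide",
        "ft guide": "FTGuide",
        "ft_guide": "FTGuide",
        "scalpel knife": "Scalpel",
    }
)


class LabelingError(ValueError):
    """Raised when a folder name or token cannot be mapped to labels."""


def canonical_label(token: str) -> str:
    """Resolve a (case-insensitive, possibly aliased) token to its canonical name."""
    name = _CANONICAL.get(token.strip().lower())
    if name is None:
        raise LabelingError(f"unknown label token: {token!r}")
    return name


@dataclass(frozen=True)
class LabelVector:
    """Length-10 binary multilabel vector aligned to :data:`TOOL_NAMES`."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != N_LABELS:
            raise ValueError(f"expected {N_LABELS} bits, got {len(self.bits)}")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("label vector entries must be 0 or 1")

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "LabelVector":
        bits = [0] * N_LABELS
        for lab in labels:
            bits[LABEL_INDEX[canonical_label(lab)]] = 1
        return cls(tuple(bits))

    @classmethod
    def from_array(cls, arr: Sequence[int] | np.ndarray) -> "LabelVector":
        return cls(tuple(int(round(float(v))) for v in arr))

    def to_labels(self) -> frozenset[str]:
        return frozenset(TOOL_NAMES[i] for i, b in enumerate(self.bits) if b)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.float32)

    def __iter__(self):
        return iter(self.bits)


@dataclass(frozen=True)
class PhaseSpec:
    """A surgical phase: ordered id, human-readable name, right-phase tool set."""

    id: str
    name: str
    tools: frozenset[str]

    def __post_init__(self) -> None:
        if ENVIRONMENT in self.tools:
            raise ValueError("Environment is never a phase tool")


def _phase(pid: str, name: str, *tools: str) -> PhaseSpec:
    return PhaseSpec(pid, name, frozenset(tools))


#: The eleven phases of the open cranial vault remodeling workflow, in order.
PHASES: tuple[PhaseSpec, ...] = (
    _phase("P1", "Skin incision", "Scalpel"),
    _phase("P2", "Cranial surface exposure", "Osteotome", "Forceps"),
    _phase("P3", "Surgical cutting guides placement", "SOGuide", "FTGuide"),
    _phase("P4", "Fixation of registration pins", "SOGuide", "FTGuide", "Handpiece"),
    _phase("P5", "Registration", "Pointer", "SOGuide", "FTGuide"),
    _phase("P6", "Frontal bone osteotomy", "Motor"),
    _phase("P7", "SO bar bone osteotomy", "Motor", "Osteotome"),
    _phase("P8", "Intraoperative navigation of remodeled bones", "Pointer"),
    _phase("P9", "Screwing", "Handpiece", "Forceps"),
    _phase("P10", "Skin placement", "Forceps"),
    _phase("P11", "Suturing", "Scissors", "Forceps"),
)

PHASE_BY_ID: dict[str, PhaseSpec] = {p.id: p for p in PHASES}
PHASE_ORDER: dict[str, int] = {p.id: i for i, p in enumerate(PHASES)}


def phase_tools(phase_id: str) -> frozenset[str]:
    """Return the fixed right-phase tool set of ``phase_id`` (Environment excluded)."""
    try:
        return PHASE_BY_ID[phase_id].tools
    except KeyError:
        raise KeyError(f"unknown phase id: {phase_id!r}") from None


def encode_folder_name(name: str) -> LabelVector:
    """Encode an underscore-joined folder name into a :class:`LabelVector`.

    Tokens are matched case-insensitively with aliases for prose spellings
    ("SO guide" -> SOGuide).  An optional variant tag after the first ``.``
    is ignored, so two folders may carry the same label set (e.g.
    ``Environment.phantom`` and ``Environment.hands``).
    """
    stem = name.split(".", 1)[0]
    tokens = [t for t in stem.split("_") if t]
    if not tokens:
        raise LabelingError(f"empty folder name: {name!r}")
    return LabelVector.from_labels(tokens)


def folder_name_for(labels: Iterable[str], variant: str | None = None) -> str:
    """Inverse of :func:`encode_folder_name`: canonical underscore-joined name.

    Labels are emitted in canonical index order; an optional ``variant`` tag
    is appended after a ``.`` to disambiguate folders with equal label sets.
    """
    canon = sorted({canonical_label(l) for l in labels}, key=LABEL_INDEX.__getitem__)
    if not canon:
        raise LabelingError("cannot name a folder for an empty label set")
    base = "_".join(canon)
    return f"{base}.{variant}" if variant else base


@dataclass
class Timeline:
    """Ground-truth phase segmentation of a frame sequence.

    ``segments`` is an ordered list of ``(phase_id, start, end)`` with
    integer, inclusive frame endpoints.  Segments must be contiguous,
    non-overlapping, and in strict P1..P11 order.
    """

    segments: list[tuple[str, int, int]] = field(default_factory=list)
    frame_rate: float = 15.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = None
        prev_order = -1
        for pid, start, end in self.segments:
            if pid not in PHASE_BY_ID:
                raise ValueError(f"unknown phase id {pid!r}")
            if start > end:
                raise ValueError(f"segment {pid}: start {start} > end {end}")
            if PHASE_ORDER[pid] <= prev_order:
                raise ValueError(f"phase {pid} out of order")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError(
                    f"segments must be contiguous: {pid} starts at {start}, "
                    f"previous ended at {prev_end}"
                )
            prev_order = PHASE_ORDER[pid]
            prev_end = end
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return 0 if not self.segments else self.segments[-1][2] + 1

    def phase_at(self, frame: int) -> str:
        for pid, start, end in self.segments:
            if start <= frame <= end:
                return pid
        raise KeyError(f"frame {frame} not covered by timeline")

    def interval(self, phase_id: str) -> tuple[int, int]:
        for pid, start, end in self.segments:
            if pid == phase_id:
                return (start, end)
        raise KeyError(f"phase {phase_id} not in timeline")

    def to_json(self) -> str:
        return json.dumps(
            {
                "frame_rate": self.frame_rate,
                "segments": [
                    {"phase": pid, "start": s, "end": e} for pid, s, e in self.segments
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Timeline":
        obj = json.loads(text)
        return cls(
            segments=[(d["phase"], int(d["start"]), int(d["end"])) for d in obj["segments"]],
            frame_rate=float(obj.get("frame_rate", 15.0)),
        )


def phases_to_json(phases: Sequence[PhaseSpec] = PHASES) -> str:
    """Export phase specifications as JSON so other vocabularies can be substituted."""
    return json.dumps(
        [{"id": p.id, "name": p.name, "tools": sorted(p.tools)} for p in phases],
        indent=2,
    )


def phases_from_json(text: str) -> tuple[PhaseSpec, ...]:
    return tuple(
        PhaseSpec(d["id"], d["name"], frozenset(d["tools"])) for d in json.loads(text)
    )
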