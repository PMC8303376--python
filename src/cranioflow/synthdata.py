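"""Synthetic scenes, surgery videos, and noisy detection logs.

The recordings this package targets — tabletop surgical simulations on an
infant-head phantom over a green surgical sheet, filmed from above under
varying illumination — are not publicly available.  This module emulates
their statistical structure so every other component can be exercised:

* :func:`render_frame` draws a green-cloth background with wrinkle noise,
  a skin-toned phantom blob, one distinct colored glyph per requested
  tool (randomised position/rotation), an optional blue-glove occluder,
  and global illumination changes.
* :func:`generate_training_set` writes label-combination folders of PNG
  frames mirroring the thirteen-video training corpus (the eleven phase
  tool combinations, the phantom alone, and empty gloved hands).
* :func:`generate_surgery_video` renders a full workflow traversal from a
  ground-truth :class:`~cranioflow.labelspace.Timeline`.
* :func:`simulate_detection_log` bypasses the CNN entirely, producing a
  detection log with controlled label flips, boundary jitter, and frame
  dropouts, so phase estimation can be tested in isolation.

Everything is deterministic given a seed: identical seeds reproduce
identical folder trees and logs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .detector import DetectionLog, DetectionRecord
from .labelspace import (
    ENVIRONMENT,
    LABEL_INDEX,
    TOOL_NAMES,
    LabelVector,
    PHASES,
    Timeline,
    folder_name_for,
    phase_tools,
)

__all__ = [
    "SceneConfig",
    "NoiseModel",
    "GLYPHS",
    "render_frame",
    "default_combinations",
    "generate_training_set",
    "default_timeline",
    "generate_surgery_video",
    "write_video_frames",
    "simulate_detection_log",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the procedural scene renderer.

    size: edge length of the square frame in pixels (>= 32).
    bg_color: base RGB of the green surgical sheet.
    wrinkle_amp: amplitude of the low-frequency brightness noise that
        stands in for cloth wrinkles.
    brightness_range: multiplicative illumination scale sampled per frame
        (natural/artificial light variation).
    gradient: when True, an additional linear shading gradient is applied
        (moving shadows).
    occluder_prob: probability of a blue-glove ellipse partially covering
        the scene.
    occluder_size: (min, max) fraction of the frame edge for the glove.
    environment_always: when True the phantom/backdrop is rendered in every
        scene, so the Environment bit is always set.
    """

    size: int = 64
    bg_color: tuple[int, int, int] = (44, 118, 74)
    wrinkle_amp: float = 0.18
    brightness_range: tuple[float, float] = (0.65, 1.3)
    gradient: bool = True
    occluder_prob: float = 0.35
    occluder_size: tuple[float, float] = (0.25, 0.45)
    environment_always: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.brightness_range[0] <= 0:
            raise ValueError("brightness scale must be > 0")
        if not 0 <= self.occluder_prob <= 1:
            raise ValueError("occluder_prob must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Detection-noise model standing in for CNN misclassifications.

    flip_rate: per-frame, per-label probability of toggling a detection.
    jitter: maximum random shift (frames) applied to segment boundaries.
    dropout_rate: probability that a frame's detections are emptied.
    """

    flip_rate: float = 0.0
    jitter: int = 0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("flip_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


# One distinct (polygon, saturated color) pairing per tool.  Colors are
# chosen with well-separated chromaticities so that a mean-color statistic
# can separate tools from background regardless of illumination scaling.
GLYPHS: dict[str, dict] = {
    "Forceps": {"color": (225, 35, 35), "shape": "triangle", "scale": 0.42},
    "FTGuide": {"color": (240, 235, 50), "shape": "hexagon", "scale": 0.40},
    "Handpiece": {"color": (150, 55, 210), "shape": "rect", "scale": 0.42},
    "Motor": {"color": (255, 140, 0), "shape": "cross", "scale": 0.44},
    "Osteotome": {"color": (0, 210, 210), "shape": "bar", "scale": 0.48},
    "Pointer": {"color": (255, 100, 175), "shape": "needle", "scale": 0.48},
    "Scalpel": {"color": (150, 95, 45), "shape": "blade", "scale": 0.40},
    "Scissors": {"color": (205, 0, 255), "shape": "vee", "scale": 0.44},
    "SOGuide": {"color": (45, 45, 255), "shape": "diamond", "scale": 0.42},
}

_PHANTOM_COLOR = (231, 188, 158)  # silicone skin tone
_GLOVE_COLOR = (70, 110, 215)  # blue latex


def _unit_polygon(shape: str) -> np.ndarray:
    """Vertices of the named glyph shape in [-1, 1]^2 coordinates."""
    if shape == "triangle":
        return np.array([(0, -1), (0.9, 0.8), (-0.9, 0.8)], dtype=float)
    if shape == "hexagon":
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        return np.stack([np.cos(ang), np.sin(ang)], axis=1)
    if shape == "rect":
        return np.array([(-0.9, -0.45), (0.9, -0.45), (0.9, 0.45), (-0.9, 0.45)], dtype=float)
    if shape == "cross":
        t = 0.34
        return np.array(
            [(-t, -1), (t, -1), (t, -t), (1, -t), (1, t), (t, t),
             (t, 1), (-t, 1), (-t, t), (-1, t), (-1, -t), (-t, -t)],
            dtype=float,
        )
    if shape == "bar":
        return np.array([(-1, -0.22), (1, -0.22), (1, 0.22), (-1, 0.22)], dtype=float)
    if shape == "needle":
        return np.array([(-1, -0.12), (1, 0), (-1, 0.12)], dtype=float)
    if shape == "blade":
        return np.array([(-1, 0.3), (-0.2, -0.4), (1, -0.1), (0.3, 0.5)], dtype=float)
    if shape == "vee":
        return np.array(
            [(-1, -1), (-0.55, -1), (0, -0.15), (0.55, -1), (1, -1), (0.18, 0.4),
             (0.45, 1), (-0.45, 1), (-0.18, 0.4)],
            dtype=float,
        )
    if shape == "diamond":
        return np.array([(0, -1), (0.65, 0), (0, 1), (-0.65, 0)], dtype=float)
    raise ValueError(f"unknown glyph shape {shape!r}")


def _draw_polygon(draw: ImageDraw.ImageDraw, verts: np.ndarray, color) -> None:
    draw.polygon([tuple(v) for v in verts], fill=tuple(int(c) for c in color))


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    s = cfg.size
    base = np.asarray(cfg.bg_color, dtype=float)[None, None, :]
    # low-frequency wrinkle field: coarse noise grid upsampled by replication
    cell = max(4, s // 8)
    grid = rng.uniform(-1.0, 1.0, size=(s // cell + 1, s // cell + 1))
    field = np.kron(grid, np.ones((cell, cell)))[:s, :s]
    shade = 1.0 + cfg.wrinkle_amp * field
    return base * shade[:, :, None]


def _glyph_anchors(n: int, size: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Jittered, shuffled quadrant centres so co-present tools stay separated.

    Tools in a surgical field lie side by side; drawing glyphs on distinct
    anchors keeps every requested tool visible rather than stacked.
    """
    base = np.array([(0.3, 0.3), (0.7, 0.3), (0.3, 0.7), (0.7, 0.7)]) * size
    order = rng.permutation(len(base))
    anchors = []
    for i in range(n):
        cx, cy = base[order[i % len(base)]]
        anchors.append(
            (cx + rng.uniform(-0.07, 0.07) * size, cy + rng.uniform(-0.07, 0.07) * size)
        )
    return anchors


def _place_glyph(
    draw: ImageDraw.ImageDraw,
    tool: str,
    centre: tuple[float, float],
    cfg: SceneConfig,
    rng: np.random.Generator,
) -> None:
    """Draw one tool glyph, optionally partially occluded by a gloved hand.

    Occlusion is a small glove-colored patch at the glyph's edge, so the
    tool stays identifiable: hands hold tools, they do not hide them.
    """
    g = GLYPHS[tool]
    s = cfg.size
    radius = 0.5 * g["scale"] * s * rng.uniform(0.8, 1.1)
    theta = rng.uniform(0.0, 2 * np.pi)
    cx, cy = centre
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    verts = _unit_polygon(g["shape"]) @ rot.T * radius + np.array([cx, cy])
    _draw_polygon(draw, verts, g["color"])
    if rng.uniform() < cfg.occluder_prob:
        phi = rng.uniform(0.0, 2 * np.pi)
        d = radius * rng.uniform(0.9, 1.2)
        r_occ = radius * rng.uniform(0.4, 0.6)
        ox, oy = cx + d * np.cos(phi), cy + d * np.sin(phi)
        draw.ellipse([ox - r_occ, oy - r_occ, ox + r_occ, oy + r_occ], fill=_GLOVE_COLOR)


def render_frame(
    tools: Iterable[str],
    cfg: SceneConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, LabelVector]:
    """Render one scene and its ground-truth label vector.

    ``tools`` is any subset of the label vocabulary; non-tool entries
    (Environment) only affect the label vector.  Returns an ``uint8``
    (size, size, 3) image.  The Environment bit is set whenever the
    phantom/backdrop is rendered, which is always under the default
    configuration.
    """
    cfg = cfg or SceneConfig()
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    tool_set = {t for t in tools}
    unknown = tool_set - set(LABEL_INDEX)
    if unknown:
        raise ValueError(f"unknown tools: {sorted(unknown)}")

    img_arr = _background(cfg, rng)
    img = Image.fromarray(np.clip(img_arr, 0, 255).astype(np.uint8))
    draw = ImageDraw.Draw(img)
    s = cfg.size

    if cfg.environment_always:
        # phantom head: skin-toned ellipse near a frame edge
        w = rng.uniform(0.3, 0.5) * s
        h = rng.uniform(0.25, 0.4) * s
        x0 = rng.uniform(-0.1 * s, s - 0.6 * w)
        y0 = rng.choice([rng.uniform(-0.15 * s, 0.05 * s), rng.uniform(0.75 * s, 0.9 * s)])
        draw.ellipse([x0, y0, x0 + w, y0 + h], fill=_PHANTOM_COLOR)

    # free-standing gloved hand, drawn under the tools so nothing is hidden
    if rng.uniform() < cfg.occluder_prob:
        lo, hi = cfg.occluder_size
        w = rng.uniform(lo, hi) * s
        h = rng.uniform(lo, hi) * s
        x0 = rng.uniform(-0.2 * s, s - 0.5 * w)
        y0 = rng.uniform(0.4 * s, s - 0.3 * h)
        draw.ellipse([x0, y0, x0 + w, y0 + h], fill=_GLOVE_COLOR)

    drawn_tools = sorted(tool_set - {ENVIRONMENT}, key=LABEL_INDEX.__getitem__)
    anchors = _glyph_anchors(len(drawn_tools), s, rng)
    for tool, anchor in zip(drawn_tools, anchors):
        _place_glyph(draw, tool, anchor, cfg, rng)

    out = np.asarray(img, dtype=float)
    scale = rng.uniform(*cfg.brightness_range)
    out = out * scale
    if cfg.gradient:
        slope = rng.uniform(-0.25, 0.25)
        ramp = 1.0 + slope * (np.arange(s) / max(s - 1, 1) - 0.5)
        out = out * ramp[None, :, None]
    image = np.clip(out, 0, 255).astype(np.uint8)

    labels = set(tool_set)
    if cfg.environment_always:
        labels.add(ENVIRONMENT)
    return image, LabelVector.from_labels(labels)


def default_combinations() -> list[tuple[frozenset[str], str | None]]:
    """The thirteen label combinations of the training corpus.

    The eleven phase tool sets (each with Environment), the phantom alone,
    and an empty-gloved-hands variant of the background.  Variant tags
    disambiguate the two Environment-only folders.
    """
    combos: list[tuple[frozenset[str], str | None]] = [
        (p.tools | {ENVIRONMENT}, None) for p in PHASES
    ]
    combos.append((frozenset({ENVIRONMENT}), None))
    combos.append((frozenset({ENVIRONMENT}), "hands"))
    return combos


def spread_counts(total: int, n: int) -> list[int]:
    """Split ``total`` into ``n`` near-even integer parts (first parts larger)."""
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


def generate_training_set(
    combinations: Sequence[frozenset[str] | tuple[frozenset[str], str | None]],
    frames_per_combination: int | Sequence[int],
    cfg: SceneConfig | None = None,
    out_dir: str | Path = "training",
    seed: int | None = None,
) -> Path:
    """Write one folder of PNG frames per label combination.

    Folders are named by the canonical underscore-joined label names (the
    inverse of folder-name encoding).  A ``manifest.json`` records the
    seed and per-folder counts.  Each folder gets an independent child
    seed, so background texture varies between folders as it did between
    the original video streams; the ``hands`` variant forces the glove
    occluder into every frame.
    """
    if not combinations:
        raise ValueError("combinations must be non-empty")
    cfg = cfg or SceneConfig()
    seed = cfg.seed if seed is None else seed
    combos: list[tuple[frozenset[str], str | None]] = [
        c if isinstance(c, tuple) else (frozenset(c), None) for c in combinations
    ]
    if isinstance(frames_per_combination, int):
        counts = [frames_per_combination] * len(combos)
    else:
        counts = list(frames_per_combination)
    if len(counts) != len(combos) or any(c < 1 for c in counts):
        raise ValueError("need one positive frame count per combination")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).spawn(len(combos))
    manifest: dict = {"seed": seed, "size": cfg.size, "folders": {}}
    for (labels, variant), count, child in zip(combos, counts, child_seeds):
        folder_cfg = cfg
        if variant == "hands":
            folder_cfg = dataclasses.replace(cfg, occluder_prob=1.0)
        name = folder_name_for(labels, variant)
        folder = out / name
        folder.mkdir(exist_ok=True)
        rng = np.random.default_rng(child)
        for i in range(count):
            image, _ = render_frame(labels, folder_cfg, rng)
            Image.fromarray(image).save(folder / f"frame_{i:05d}.png")
        manifest["folders"][name] = {
            "labels": sorted(labels, key=LABEL_INDEX.__getitem__),
            "count": count,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def default_timeline(n_frames: int = 4920, frame_rate: float = 15.0) -> Timeline:
    """An eleven-phase ground-truth timeline over ``n_frames`` frames.

    Per-phase durations of the original recording are not known, so the
    frames are split as evenly as integer division allows.
    """
    counts = spread_counts(n_frames, len(PHASES))
    segments = []
    start = 0
    for phase, count in zip(PHASES, counts):
        segments.append((phase.id, start, start + count - 1))
        start += count
    return Timeline(segments, frame_rate=frame_rate)


def generate_surgery_video(
    timeline: Timeline,
    cfg: SceneConfig | None = None,
    seed: int | None = None,
) -> tuple[list[np.ndarray], list[LabelVector], Timeline]:
    """Render a full workflow traversal frame by frame.

    Frame ``t`` shows the right-phase tools of the phase covering ``t``;
    illumination varies within phases per the scene configuration.  The
    input timeline is returned verbatim as ground truth.
    """
    timeline.validate()
    if not timeline.segments:
        raise ValueError("timeline has no segments")
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    frames: list[np.ndarray] = []
    labels: list[LabelVector] = []
    for pid, start, end in timeline.segments:
        tools = phase_tools(pid)
        for _ in range(start, end + 1):
            image, vec = render_frame(tools, cfg, rng)
            frames.append(image)
            labels.append(vec)
    return frames, labels, timeline


def write_video_frames(frames: Sequence[np.ndarray], out_dir: str | Path) -> Path:
    """Write frames as ``frame_%05d.png`` (a frame directory stands in for video)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        Image.fromarray(frame).save(out / f"frame_{i:05d}.png")
    return out


def simulate_detection_log(
    timeline: Timeline,
    noise: NoiseModel | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> DetectionLog:
    """Produce a noisy detection log directly from a ground-truth timeline.

    The per-frame detected set starts as the right-phase tools (plus
    Environment), then segment boundaries are jittered, individual labels
    are flipped, and whole frames are dropped out per the noise model.
    Probabilities are fixed at 0.9 for detected and 0.1 for undetected
    labels — constants on either side of the threshold keep tests exact.
    """
    timeline.validate()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    n = timeline.n_frames

    # jittered segment boundaries (the last end stays pinned)
    bounds = [end for _, _, end in timeline.segments]
    jittered = []
    prev = -1
    for i, b in enumerate(bounds):
        if i == len(bounds) - 1 or noise.jitter == 0:
            jb = b
        else:
            jb = b + int(rng.integers(-noise.jitter, noise.jitter + 1))
        jb = min(max(jb, prev + 1), n - 1 - (len(bounds) - 1 - i))
        jittered.append(jb)
        prev = jb

    phase_of_frame: list[str] = []
    start = 0
    for (pid, _, _), jb in zip(timeline.segments, jittered):
        phase_of_frame.extend([pid] * (jb - start + 1))
        start = jb + 1

    records: list[DetectionRecord] = []
    for t in range(n):
        detected = set(phase_tools(phase_of_frame[t])) | {ENVIRONMENT}
        if noise.flip_rate > 0:
            flips = rng.uniform(size=len(TOOL_NAMES)) < noise.flip_rate
            for name, flip in zip(TOOL_NAMES, flips):
                if flip:
                    detected ^= {name}
        if noise.dropout_rate > 0 and rng.uniform() < noise.dropout_rate:
            detected = set()
        probs = tuple(0.9 if name in detected else 0.1 for name in TOOL_NAMES)
        records.append(
            DetectionRecord(
                frame=t,
                time_s=t / timeline.frame_rate,
                probabilities=probs,
                detected=frozenset(detected),
            )
        )
    return DetectionLog(records, frame_rate=timeline.frame_rate, threshold=threshold)
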