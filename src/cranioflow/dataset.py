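"""Frame loading, preprocessing, train/validation split, and augmentation.

Training data lives in label-combination folders: every frame in a folder
named ``Environment_Forceps_Osteotome`` carries exactly those labels.
Images are resized to 64x64 and normalised to [0, 1].  The split shuffles
the pool and partitions it 80:20.  Augmentation applies random rotation,
shifts, shear, zoom, and horizontal flips within configured ranges,
sampled on the fly per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TypeVar

import numpy as np
from PIL import Image
from scipy import ndimage

from .labelspace import LabelVector, LabelingError, encode_folder_name

__all__ = [
    "AugmentConfig",
    "SplitSpec",
    "IMAGE_SIZE",
    "load_image",
    "load_labeled_frames",
    "preprocess",
    "split_dataset",
    "sample_augment_params",
    "augment",
]

IMAGE_SIZE = 64

_T = TypeVar("_T")


@dataclass(frozen=True)
class AugmentConfig:
    """Geometric augmentation ranges.

    rotation_deg: rotation angle sampled uniformly in +/- this many degrees.
    width_shift / height_shift: translation as a fraction of the image edge.
    shear: shear intensity (off-diagonal affine coefficient), +/- this value.
    zoom: scale factor sampled in [1 - zoom, 1 + zoom].
    horizontal_flip: when True each sample is mirrored with probability 0.5.
    """

    rotation_deg: float = 15.0
    width_shift: float = 0.10
    height_shift: float = 0.10
    shear: float = 0.50
    zoom: float = 0.10
    horizontal_flip: bool = True

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "width_shift", "height_shift", "shear", "zoom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "AugmentConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass(frozen=True)
class SplitSpec:
    """Shuffled train/validation partition (default 80:20)."""

    train_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG frame as an uint8 RGB array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def load_labeled_frames(root: str | Path) -> list[tuple[np.ndarray, LabelVector]]:
    """Load every frame under label-combination folders of ``root``.

    Each image is paired with the vector encoded from its folder name.
    Paths are sorted, so the order is deterministic.  A folder whose name
    cannot be decoded raises :class:`~cranioflow.labelspace.LabelingError`.
    """
    root = Path(root)
    folders = sorted(p for p in root.iterdir() if p.is_dir())
    if not folders:
        raise LabelingError(f"no label-combination folders under {root}")
    items: list[tuple[np.ndarray, LabelVector]] = []
    for folder in folders:
        vec = encode_folder_name(folder.name)
        for path in sorted(folder.iterdir()):
            if path.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                items.append((load_image(path), vec))
    return items


def preprocess(image: np.ndarray, size: int = IMAGE_SIZE) -> np.ndarray:
    """Resize to ``size`` x ``size`` and scale intensities to [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected an HxWx3 image, got shape {arr.shape}")
    if arr.dtype == np.float32 or arr.dtype == np.float64:
        arr = np.clip(arr, 0.0, 1.0)
        arr = (arr * 255).astype(np.uint8)
    if arr.shape[:2] != (size, size):
        arr = np.asarray(Image.fromarray(arr).resize((size, size), Image.BILINEAR))
    return arr.astype(np.float32) / 255.0


def split_dataset(
    items: Sequence[_T], spec: SplitSpec | None = None
) -> tuple[list[_T], list[_T]]:
    """Shuffle and partition ``items`` into train/validation lists.

    Train size is ``round(train_fraction * n)``; the two parts are
    disjoint and together cover the input.  With the default 80:20 split,
    9,934 items partition as 7,947:1,987.
    """
    spec = spec or SplitSpec()
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    perm = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [items[i] for i in perm[:n_train]]
    val = [items[i] for i in perm[n_train:]]
    return train, val


def sample_augment_params(
    cfg: AugmentConfig, rng: np.random.Generator
) -> dict[str, float | bool]:
    """Draw one set of augmentation parameters, each uniform in its range."""
    return {
        "angle": float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)),
        "tx": float(rng.uniform(-cfg.width_shift, cfg.width_shift)),
        "ty": float(rng.uniform(-cfg.height_shift, cfg.height_shift)),
        "shear": float(rng.uniform(-cfg.shear, cfg.shear)),
        "zoom": float(rng.uniform(1.0 - cfg.zoom, 1.0 + cfg.zoom)),
        "flip": bool(cfg.horizontal_flip and rng.uniform() < 0.5),
    }


def _affine_matrix(params: dict, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Output->input affine map (matrix, offset) about the image centre."""
    theta = np.deg2rad(params["angle"])
    cos, sin = np.cos(theta), np.sin(theta)
    # row/col convention: coordinates are (row, col)
    rot = np.array([[cos, -sin], [sin, cos]])
    shear = np.array([[1.0, params["shear"]], [0.0, 1.0]])
    zoom = params["zoom"] * np.eye(2)
    flip = np.array([[1.0, 0.0], [0.0, -1.0 if params["flip"] else 1.0]])
    fwd = rot @ shear @ zoom @ flip
    inv = np.linalg.inv(fwd)
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([params["ty"] * h, params["tx"] * w])
    offset = centre - inv @ (centre + shift)
    return inv, offset


def augment(
    image: np.ndarray,
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | int | None = None,
    params: dict | None = None,
) -> np.ndarray:
    """Apply one random geometric transform to a preprocessed image.

    Out-of-bounds pixels are filled by nearest-edge replication so no
    label-correlated borders are introduced.  Supplying ``params``
    (as from :func:`sample_augment_params`) bypasses sampling, which is
    how deterministic transforms (e.g. a forced flip) are obtained.
    """
    cfg = cfg or AugmentConfig()
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3:
        raise ValueError("augment expects an HxWxC image")
    if params is None:
        if rng is None or isinstance(rng, int):
            rng = np.random.default_rng(rng)
        params = sample_augment_params(cfg, rng)
    if (
        params["angle"] == 0.0
        and params["tx"] == 0.0
        and params["ty"] == 0.0
        and params["shear"] == 0.0
        and params["zoom"] == 1.0
    ):
        # pure flip (or identity): exact, no interpolation
        return img[:, ::-1, :].copy() if params["flip"] else img.copy()
    h, w = img.shape[:2]
    matrix, offset = _affine_matrix(params, h, w)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[:, :, c] = ndimage.affine_transform(
            img[:, :, c], matrix, offset=offset, order=1, mode="nearest"
        )
    return np.clip(out, 0.0, 1.0)
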