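"""Image and polygon-label I/O plus preprocessing.

Datasets handled here pair an 8-bit grayscale radiograph with a plain-text
label file in the YOLO segmentation dialect: one region per line, an integer
class id followed by an even-length run of polygon vertex coordinates
normalized to [0, 1] by image width and height.

Coordinate convention: origin at the image's top-left corner, x rightward,
y downward. Coordinates are continuous; pixel centers sit at integer
coordinates (no half-pixel offset). Vertices are polygon corners in drawing
order, with closure implicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

#: Pathology class names in canonical label order (class id 0..8).
CLASS_NAMES = (
    "Consolidation",
    "Effusion",
    "Fibrosis",
    "Pneumonia",
    "Pneumothorax",
    "No Finding",
    "Nodule",
    "Atelectasis",
    "Infiltration",
)

N_CLASSES = len(CLASS_NAMES)

#: Normalized coordinates may overshoot [0, 1] by at most this much (float
#: dust from upstream tools); they are clamped. Larger overshoot is an error.
COORD_SLACK = 1e-6


class LabelFormatError(ValueError):
    """A label file line violates the polygon-label grammar."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with an explicit intensity-scale tag.

    ``scale`` is ``"eight_bit"`` (intensities in [0, 255]) or ``"unit"``
    (intensities in [0, 1]).
    """

    pixels: np.ndarray
    scale: str = "eight_bit"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.scale not in ("eight_bit", "unit"):
            raise ValueError(f"unknown intensity scale {self.scale!r}")
        hi = 255.0 if self.scale == "eight_bit" else 1.0
        if px.min() < -COORD_SLACK or px.max() > hi * (1 + COORD_SLACK):
            raise ValueError(
                f"intensities outside the declared {self.scale!r} range"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PolygonAnnotation:
    """A single polygonal region: class id plus normalized vertices."""

    class_id: int
    vertices: np.ndarray  # (n, 2) float array, columns (x, y), in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a polygon needs at least 3 (x, y) vertices")
        if v.min() < -COORD_SLACK or v.max() > 1 + COORD_SLACK:
            raise ValueError("normalized coordinates must lie in [0, 1]")
        v = np.clip(v, 0.0, 1.0)
        object.__setattr__(self, "vertices", v)
        if not (0 <= int(self.class_id)):
            raise ValueError("class_id must be a nonnegative integer")

    def with_vertices(self, vertices: np.ndarray) -> "PolygonAnnotation":
        return PolygonAnnotation(self.class_id, vertices)


@dataclass
class LabeledImage:
    """An image together with its polygon annotations."""

    image: GrayImage
    annotations: list[PolygonAnnotation] = field(default_factory=list)
    source_id: str = ""


# ---------------------------------------------------------------------------
# Label file I/O
# ---------------------------------------------------------------------------

def read_label_file(path: str | Path, classes: int = N_CLASSES) -> list[PolygonAnnotation]:
    """Parse a polygon label file.

    Each non-empty line must be ``class_id x1 y1 x2 y2 ...`` with at least
    three vertices; coordinates must be normalized to [0, 1]. Malformed lines
    raise :class:`LabelFormatError` naming the 1-based line number.
    """
    path = Path(path)
    annotations: list[PolygonAnnotation] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        try:
            class_id = int(tokens[0])
        except ValueError:
            raise LabelFormatError(f"{path}:{lineno}: class id {tokens[0]!r} is not an integer")
        if not 0 <= class_id < classes:
            raise LabelFormatError(
                f"{path}:{lineno}: class id {class_id} outside 0..{classes - 1}"
            )
        coords = tokens[1:]
        if len(coords) % 2 != 0:
            raise LabelFormatError(f"{path}:{lineno}: odd coordinate count ({len(coords)})")
        if len(coords) < 6:
            raise LabelFormatError(f"{path}:{lineno}: fewer than 3 vertices")
        try:
            values = np.array([float(t) for t in coords], dtype=float)
        except ValueError:
            raise LabelFormatError(f"{path}:{lineno}: non-numeric coordinate")
        if values.min() < -COORD_SLACK or values.max() > 1 + COORD_SLACK:
            raise LabelFormatError(f"{path}:{lineno}: coordinate outside [0, 1]")
        annotations.append(PolygonAnnotation(class_id, values.reshape(-1, 2)))
    return annotations


def write_label_file(annotations: Sequence[PolygonAnnotation], path: str | Path) -> None:
    """Write annotations in the polygon-label dialect, 6-decimal fixed point."""
    path = Path(path)
    lines = []
    for ann in annotations:
        coords = " ".join(f"{v:.6f}" for v in ann.vertices.ravel())
        lines.append(f"{int(ann.class_id)} {coords}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> GrayImage:
    """Read a PNG/JPEG as an 8-bit grayscale image."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return GrayImage(arr, scale="eight_bit")


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write an image as 8-bit grayscale PNG/JPEG (by extension)."""
    px = img.pixels
    if img.scale == "unit":
        px = px * 255.0
    Image.fromarray(np.clip(np.rint(px), 0, 255).astype(np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def normalize_intensity(img: GrayImage) -> GrayImage:
    """Min–max rescale intensities to [0, 1].

    ``out = (x - x_min) / (x_max - x_min)`` per pixel. A constant image has
    no range; it maps to all zeros with a warning.
    """
    px = np.asarray(img.pixels, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        warnings.warn("constant image: intensity range is zero, output all zeros")
        return GrayImage(np.zeros_like(px), scale="unit")
    return GrayImage((px - lo) / (hi - lo), scale="unit")


def resize_image(img: GrayImage, target: tuple[int, int] = (800, 800)) -> GrayImage:
    """Resize to ``target`` (width, height) with bilinear interpolation."""
    tw, th = int(target[0]), int(target[1])
    if tw <= 0 or th <= 0:
        raise ValueError("target dimensions must be positive")
    if (img.width, img.height) == (tw, th):
        return img
    out = _sk_resize(
        np.asarray(img.pixels, dtype=float),
        (th, tw),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
        clip=True,
    )
    return GrayImage(out, scale=img.scale)


# ---------------------------------------------------------------------------
# Coordinate (de)normalization
# ---------------------------------------------------------------------------

def denormalize_coords(points: np.ndarray | PolygonAnnotation, width: int, height: int) -> np.ndarray:
    """Map normalized (x, y) pairs to absolute pixel coordinates."""
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    if isinstance(points, PolygonAnnotation):
        points = points.vertices
    pts = np.asarray(points, dtype=float)
    return pts * np.array([width, height], dtype=float)


def normalize_coords(points: np.ndarray, width: int, height: int) -> np.ndarray:
    """Map absolute pixel (x, y) pairs to [0, 1], clamped at the frame."""
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    pts = np.asarray(points, dtype=float) / np.array([width, height], dtype=float)
    return np.clip(pts, 0.0, 1.0)


def load_class_names(path: str | Path | None = None) -> tuple[str, ...]:
    """Load class names from a YAML list, or return the built-in order."""
    if path is None:
        return CLASS_NAMES
    import yaml

    names = yaml.safe_load(Path(path).read_text())
    if not isinstance(names, list) or not all(isinstance(n, str) for n in names):
        raise ValueError("class-name file must be a YAML list of strings")
    return tuple(names)
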