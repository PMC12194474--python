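"""Radiograph phantom generator with exact polygon ground truth.

Phantoms emulate the structural features the augmentation pipeline assumes
about frontal chest radiographs: an 800×800 8-bit frame, a brighter
mediastinal/soft-tissue background with mild texture, two darker elliptical
lung fields, and 0–4 lesion polygons whose classes follow a configurable
imbalanced frequency vector. Every lesion is rendered as a soft additive
intensity perturbation, and its annotation is the exact generating polygon,
so pixel–label alignment is known by construction — which is what makes
phantoms usable as ground truth for alignment and metric tests.

They are not photorealistic: no ribs, heart shadow, devices, or acquisition
physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .formats import (
    CLASS_NAMES,
    GrayImage,
    LabeledImage,
    N_CLASSES,
    PolygonAnnotation,
    normalize_coords,
    write_image,
    write_label_file,
)
from .geometry import polygon_area, rasterize_polygon

#: Class frequencies mirroring the imbalance of a curated clinical training
#: set: Fibrosis and Nodule common (~20–26%), Atelectasis and Pneumothorax
#: rare (~1–5%). Proportional to per-class training image counts
#: (215, 234, 511, 244, 99, 180, 378, 16, 55).
IMBALANCED_COUNTS = (215, 234, 511, 244, 99, 180, 378, 16, 55)
IMBALANCED_FREQUENCIES = tuple(c / sum(IMBALANCED_COUNTS) for c in IMBALANCED_COUNTS)

#: (cx, cy, semi_x, semi_y) as fractions of width/height, per lung.
DEFAULT_LUNGS = (
    (0.32, 0.45, 0.16, 0.28),
    (0.68, 0.45, 0.16, 0.28),
)


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom population."""

    image_size: tuple[int, int] = (800, 800)  # (width, height)
    class_frequencies: tuple[float, ...] = IMBALANCED_FREQUENCIES
    lesions_per_image: tuple[int, int] = (0, 4)
    lesion_area_range: tuple[float, float] = (500.0, 20000.0)
    lung_ellipses: tuple[tuple[float, float, float, float], ...] = DEFAULT_LUNGS
    background_texture: float = 6.0  # noise std, 8-bit scale
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_frequencies) != N_CLASSES:
            raise ValueError(f"need {N_CLASSES} class frequencies")
        if any(f < 0 for f in self.class_frequencies) or sum(self.class_frequencies) == 0:
            raise ValueError("class frequencies must be nonnegative and not all zero")
        lo, hi = self.lesion_area_range
        if not 0 < lo <= hi:
            raise ValueError("lesion_area_range must be positive and ordered")
        w, h = self.image_size
        for cx, cy, ax, ay in self.lung_ellipses:
            if cx - ax < 0 or cx + ax > 1 or cy - ay < 0 or cy + ay > 1:
                raise ValueError("lung ellipse extends outside the frame")


def _lesion_polygon(
    rng: np.random.Generator, center: np.ndarray, area: float
) -> np.ndarray:
    """Convex-ish star polygon (8–16 vertices) rescaled to the target area."""
    n = int(rng.integers(8, 17))
    angles = np.sort(rng.uniform(0.0, 2 * np.pi, n))
    radii = 1.0 + 0.3 * rng.uniform(-1.0, 1.0, n)
    pts = np.column_stack([np.cos(angles), np.sin(angles)]) * radii[:, None]
    pts *= np.sqrt(area / polygon_area(pts))
    return pts + center


def generate_phantom(config: PhantomConfig, rng: np.random.Generator) -> LabeledImage:
    """One phantom: textured background, lung ellipses, lesion polygons.

    Lesion centroids are placed well inside a lung ellipse (at most 60% of
    the way to its border) so whole lesions stay within plausible anatomy
    and inside the frame. Lesion classes are drawn from
    ``config.class_frequencies``; annotations are the exact generating
    polygons, normalized.
    """
    w, h = config.image_size
    base = np.full((h, w), 185.0)
    if config.background_texture > 0:
        base += gaussian_filter(
            rng.normal(0.0, config.background_texture * 3.0, (h, w)), sigma=3.0
        )
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy, ax, ay in config.lung_ellipses:
        inside = ((xx - cx * w) / (ax * w)) ** 2 + ((yy - cy * h) / (ay * h)) ** 2 <= 1.0
        base[inside] -= 70.0

    freq = np.asarray(config.class_frequencies, dtype=float)
    freq = freq / freq.sum()
    n_lesions = int(rng.integers(config.lesions_per_image[0], config.lesions_per_image[1] + 1))
    annotations: list[PolygonAnnotation] = []
    for _ in range(n_lesions):
        cx, cy, ax, ay = config.lung_ellipses[rng.integers(len(config.lung_ellipses))]
        # uniform in the unit disk, shrunk so the polygon stays in the lung
        r = 0.6 * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2 * np.pi)
        center = np.array([(cx + r * ax * np.cos(phi)) * w, (cy + r * ay * np.sin(phi)) * h])
        area = float(rng.uniform(*config.lesion_area_range))
        poly = _lesion_polygon(rng, center, area)
        poly = np.clip(poly, 0.0, [w - 1.0, h - 1.0])
        class_id = int(rng.choice(N_CLASSES, p=freq))
        # soft additive blob: lesions perturb rather than replace intensity
        mask = rasterize_polygon(poly, w, h).astype(float)
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        base += sign * 35.0 * gaussian_filter(mask, sigma=2.0)
        annotations.append(PolygonAnnotation(class_id, normalize_coords(poly, w, h)))

    image = GrayImage(np.clip(base, 0.0, 255.0), scale="eight_bit")
    return LabeledImage(image, annotations)


def generate_dataset(
    n: int,
    config: PhantomConfig,
    images_dir: str | Path,
    labels_dir: str | Path,
) -> pd.DataFrame:
    """Write ``n`` phantom image/label pairs and return a manifest.

    Files are named ``phantom_{i:04d}.png`` / ``.txt``; the manifest has one
    row per image with per-class annotation counts. Generation is fully
    determined by ``config.seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    images_dir, labels_dir = Path(images_dir), Path(labels_dir)
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(n):
        item = generate_phantom(config, rng)
        stem = f"phantom_{i:04d}"
        write_image(item.image, images_dir / f"{stem}.png")
        write_label_file(item.annotations, labels_dir / f"{stem}.txt")
        counts = {name: 0 for name in CLASS_NAMES}
        for ann in item.annotations:
            counts[CLASS_NAMES[ann.class_id]] += 1
        rows.append({"image": stem, "n_annotations": len(item.annotations), **counts})
    return pd.DataFrame(rows, columns=["image", "n_annotations", *CLASS_NAMES])
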