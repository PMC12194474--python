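"""Coordinate-aware augmentation pipeline and the class-balance planner.

One sampled affine map is applied to an image's pixels (bilinear warp) and
to every polygon annotation (exact vertex transform + clipping), so the
augmented label stays aligned with the augmented image. Photometric
augmentation touches pixels only. Sampling is driven entirely by seeded
integer-state RNG streams; each source image gets its own substream derived
from the run seed and a stable hash of the file stem, so partial or parallel
runs reproduce byte-identically.

Clinical bounds (defaults): discrete rotation angles within ±10°,
translation within ±2% of width/height, isotropic scaling in 0.95–1.05,
brightness/contrast within ±10%, noise variance 10–50 (8-bit scale).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .formats import (
    LabeledImage,
    read_image,
    read_label_file,
    normalize_intensity,
    resize_image,
    write_image,
    write_label_file,
)
from .geometry import AffineTransform, compose_affine, transform_polygon, warp_image
from .photometric import PhotometricParams, add_gaussian_noise, adjust_brightness_contrast

#: Rotation-angle sets of the four augmentation scenarios. The baseline
#: scenario uses no rotation; the others use discrete ±10°, ±5°, or both.
SCENARIOS: dict[str, tuple[float, ...]] = {
    "model1": (),
    "model2": (-10.0, 10.0),
    "model3": (-5.0, 5.0),
    "model4": (-10.0, -5.0, 5.0, 10.0),
}

MAX_ROTATION_DEG = 10.0
MAX_SHIFT_FRACTION = 0.02
CLINICAL_SCALE_RANGE = (0.95, 1.05)


@dataclass(frozen=True)
class AugmentationParams:
    """Sampling configuration for one augmentation run."""

    rotation_angles: tuple[float, ...] = ()
    shift_limit: float = MAX_SHIFT_FRACTION
    scale_range: tuple[float, float] = CLINICAL_SCALE_RANGE
    photometric: PhotometricParams = field(default_factory=PhotometricParams)
    n_per_image: int = 1
    seed: int = 0
    non_clinical: bool = False  # explicit opt-out from the bounds check

    def __post_init__(self) -> None:
        if self.n_per_image < 0:
            raise ValueError("n_per_image must be >= 0")
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError("scale_range must be positive and ordered")
        if self.shift_limit < 0:
            raise ValueError("shift_limit must be nonnegative")
        if not self.non_clinical:
            if any(abs(a) > MAX_ROTATION_DEG for a in self.rotation_angles):
                raise ValueError("rotation angles exceed the ±10° clinical bound")
            if self.shift_limit > MAX_SHIFT_FRACTION + 1e-12:
                raise ValueError("shift_limit exceeds the 2% clinical bound")
            if lo < CLINICAL_SCALE_RANGE[0] - 1e-12 or hi > CLINICAL_SCALE_RANGE[1] + 1e-12:
                raise ValueError("scale_range exceeds the 0.95–1.05 clinical bound")


def scenario_params(name: str, **overrides) -> AugmentationParams:
    """AugmentationParams preset for one of the four named scenarios."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return AugmentationParams(rotation_angles=SCENARIOS[name], **overrides)


@dataclass(frozen=True)
class TransformSample:
    """One fully sampled augmentation: geometric and photometric parameters."""

    theta: float
    tx: float
    ty: float
    scale: float
    brightness: float
    contrast: float
    noise_variance: float

    def affine(self, width: int, height: int) -> AffineTransform:
        """The shared affine map, pivoting at the image center."""
        return compose_affine(
            theta=self.theta,
            tx=self.tx,
            ty=self.ty,
            sx=self.scale,
            sy=self.scale,
            center=(width / 2.0, height / 2.0),
        )


def sample_transform(
    params: AugmentationParams,
    rng: np.random.Generator,
    width: int = 800,
    height: int = 800,
) -> TransformSample:
    """Draw one augmentation's parameters from the seeded stream.

    The angle comes uniformly from the scenario's discrete set (identity
    when the set is empty); translation is uniform within ±shift_limit of
    each dimension; scaling is isotropic, uniform in scale_range; photometric
    values are uniform within their limits.
    """
    angles = params.rotation_angles
    theta = float(angles[rng.integers(len(angles))]) if angles else 0.0
    tx = float(rng.uniform(-params.shift_limit, params.shift_limit) * width)
    ty = float(rng.uniform(-params.shift_limit, params.shift_limit) * height)
    scale = float(rng.uniform(*params.scale_range))
    ph = params.photometric
    return TransformSample(
        theta=theta,
        tx=tx,
        ty=ty,
        scale=scale,
        brightness=float(rng.uniform(-ph.brightness_limit, ph.brightness_limit)),
        contrast=float(rng.uniform(-ph.contrast_limit, ph.contrast_limit)),
        noise_variance=float(rng.uniform(*ph.noise_variance_range)),
    )


def apply_sample(
    item: LabeledImage,
    sample: TransformSample,
    rng: np.random.Generator,
    min_area: float = 10.0,
) -> tuple[LabeledImage, int]:
    """Apply one sampled augmentation to an image/label pair.

    The same affine warps the pixels and every polygon; photometric changes
    touch pixels only. Returns the augmented pair and the number of
    annotations dropped by frame clipping.
    """
    w, h = item.image.width, item.image.height
    affine = sample.affine(w, h)
    img = warp_image(item.image, affine, interpolation="bilinear")
    img = adjust_brightness_contrast(img, sample.brightness, sample.contrast)
    img = add_gaussian_noise(img, sample.noise_variance, rng)
    annotations = []
    dropped = 0
    for ann in item.annotations:
        out = transform_polygon(ann, affine, w, h, min_area=min_area)
        if out is None:
            dropped += 1
        else:
            annotations.append(out)
    return LabeledImage(img, annotations, source_id=item.source_id), dropped


def augment_pair(
    item: LabeledImage,
    params: AugmentationParams,
    rng: np.random.Generator,
) -> list[LabeledImage]:
    """Produce ``params.n_per_image`` augmented copies of one labeled image."""
    outputs = []
    for _ in range(params.n_per_image):
        sample = sample_transform(params, rng, item.image.width, item.image.height)
        out, _ = apply_sample(item, sample, rng)
        outputs.append(out)
    return outputs


def _substream(seed: int, stem: str) -> np.random.Generator:
    """Per-image RNG substream: run seed plus a stable hash of the stem."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stem.encode())])


def augment_dataset(
    images_dir: str | Path,
    labels_dir: str | Path,
    out_images_dir: str | Path,
    out_labels_dir: str | Path,
    params: AugmentationParams | str = "model1",
    n: int | None = None,
    seed: int | None = None,
    manifest_path: str | Path | None = None,
) -> pd.DataFrame:
    """Augment every image/label pair in a directory tree.

    For each source image ``stem.ext`` with label file ``stem.txt``, writes
    ``n`` pairs named ``stem_aug{j}.ext`` / ``stem_aug{j}.txt`` and returns a
    manifest (one row per output) of all sampled parameters. Re-running with
    the same seed reproduces the label files byte-identically. A missing
    label file skips that image and is counted in the manifest attrs.
    """
    images_dir, labels_dir = Path(images_dir), Path(labels_dir)
    out_images_dir, out_labels_dir = Path(out_images_dir), Path(out_labels_dir)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"image directory not found: {images_dir}")
    if not labels_dir.is_dir():
        raise FileNotFoundError(f"label directory not found: {labels_dir}")
    out_images_dir.mkdir(parents=True, exist_ok=True)
    out_labels_dir.mkdir(parents=True, exist_ok=True)

    if isinstance(params, str):
        params = scenario_params(params)
    if n is not None:
        params = replace(params, n_per_image=int(n))
    if seed is not None:
        params = replace(params, seed=int(seed))

    rows = []
    errors = 0
    image_paths = sorted(
        p for p in images_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    for path in image_paths:
        label_path = labels_dir / f"{path.stem}.txt"
        if not label_path.exists():
            errors += 1
            continue
        item = LabeledImage(
            normalize_intensity(resize_image(read_image(path))),
            read_label_file(label_path),
            source_id=path.stem,
        )
        rng = _substream(params.seed, path.stem)
        for j in range(params.n_per_image):
            sample = sample_transform(params, rng, item.image.width, item.image.height)
            out, dropped = apply_sample(item, sample, rng)
            out_name = f"{path.stem}_aug{j}"
            write_image(out.image, out_images_dir / f"{out_name}{path.suffix}")
            write_label_file(out.annotations, out_labels_dir / f"{out_name}.txt")
            rows.append(
                {
                    "source": path.stem,
                    "output": out_name,
                    "theta": sample.theta,
                    "tx": sample.tx,
                    "ty": sample.ty,
                    "scale": sample.scale,
                    "brightness": sample.brightness,
                    "contrast": sample.contrast,
                    "noise_variance": sample.noise_variance,
                    "annotations_in": len(item.annotations),
                    "annotations_out": len(out.annotations),
                    "dropped": dropped,
                }
            )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "source", "output", "theta", "tx", "ty", "scale",
            "brightness", "contrast", "noise_variance",
            "annotations_in", "annotations_out", "dropped",
        ],
    )
    manifest.attrs["missing_labels"] = errors
    if manifest_path is not None:
        manifest.to_csv(manifest_path, index=False, float_format="%.9f")
    return manifest


# ---------------------------------------------------------------------------
# Class-balance planner
# ---------------------------------------------------------------------------

def plan_augmentation(rows: Iterable[tuple] | pd.DataFrame) -> pd.DataFrame:
    """Per-folder augmentation plan with a totals row.

    ``rows`` holds (folder_id, original_count, multiplier) triples; each
    folder contributes ``original × multiplier`` augmented images for a
    final count of ``original + augmented``. The returned frame appends a
    ``total`` row of column sums — the planner's arithmetic for rebalancing
    rare abnormality folders with higher multipliers.
    """
    if isinstance(rows, pd.DataFrame):
        rows = list(rows.itertuples(index=False, name=None))
    records = []
    for folder_id, original, multiplier in rows:
        original, multiplier = int(original), int(multiplier)
        if original < 0 or multiplier < 0:
            raise ValueError("counts and multipliers must be nonnegative")
        augmented = original * multiplier
        records.append(
            {
                "folder": folder_id,
                "original": original,
                "multiplier": multiplier,
                "augmented": augmented,
                "final": original + augmented,
            }
        )
    plan = pd.DataFrame(records, columns=["folder", "original", "multiplier", "augmented", "final"])
    total = {
        "folder": "total",
        "original": int(plan["original"].sum()),
        "multiplier": pd.NA,
        "augmented": int(plan["augmented"].sum()),
        "final": int(plan["final"].sum()),
    }
    return pd.concat([plan, pd.DataFrame([total])], ignore_index=True)
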