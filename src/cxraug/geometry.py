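"""Affine transforms applied identically to pixel grids and polygon vertices.

The central guarantee of coordinate-aware augmentation is that one shared
affine map transforms both the image and its vector labels, so pixel–label
alignment survives augmentation. A transform is a 3×3 homogeneous matrix
T = [R(θ) | t] · S(s_x, s_y), optionally conjugated with translations so the
rotation/scaling pivot sits at an arbitrary center (for radiographs: the
image center, so anatomy stays in frame).

Angles are user-facing degrees; conversion to radians is internal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely.geometry as sgeom
from skimage.draw import polygon as _draw_polygon
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp as _sk_warp

from .formats import GrayImage, PolygonAnnotation, denormalize_coords, normalize_coords


@dataclass(frozen=True)
class AffineTransform:
    """A 3×3 homogeneous planar affine map acting on (x, y) points."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("affine matrix must be 3×3")
        if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row of an affine matrix must be (0, 0, 1)")
        if abs(np.linalg.det(m[:2, :2])) < 1e-15:
            raise ValueError("affine matrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @property
    def det(self) -> float:
        """Determinant of the linear part (signed area scale factor)."""
        return float(np.linalg.det(self.matrix[:2, :2]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return transform_points(points, self)

    def to_list(self) -> list[float]:
        """Row-major 9-number list, for YAML reproducibility logs."""
        return [float(v) for v in self.matrix.ravel()]

    @classmethod
    def from_list(cls, values: Sequence[float]) -> "AffineTransform":
        return cls(np.asarray(values, dtype=float).reshape(3, 3))


def rotation_matrix(theta: float) -> AffineTransform:
    """Rotation by ``theta`` degrees about the origin.

    Maps (x, y) to (x cosθ − y sinθ, x sinθ + y cosθ).
    """
    r = math.radians(theta)
    c, s = math.cos(r), math.sin(r)
    return AffineTransform(np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]))


def scale_matrix(sx: float, sy: float) -> AffineTransform:
    """Axis-aligned scaling (x, y) → (s_x·x, s_y·y)."""
    if sx <= 0 or sy <= 0:
        raise ValueError("scale factors must be positive")
    return AffineTransform(np.diag([float(sx), float(sy), 1.0]))


def translation_matrix(tx: float, ty: float) -> AffineTransform:
    return AffineTransform(np.array([[1.0, 0.0, tx], [0.0, 1.0, ty], [0.0, 0.0, 1.0]]))


def compose_affine(
    theta: float = 0.0,
    tx: float = 0.0,
    ty: float = 0.0,
    sx: float = 1.0,
    sy: float = 1.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> AffineTransform:
    """Compose scaling, rotation and translation into one affine map.

    Scaling is applied first, then rotation and translation:
    ``T = [R(θ) | t] · S(s_x, s_y)``, conjugated with center translations so
    the pivot of rotation and scaling is ``center`` (default: the origin).
    """
    rt = rotation_matrix(theta).matrix.copy()
    rt[0, 2], rt[1, 2] = float(tx), float(ty)
    core = AffineTransform(rt) @ scale_matrix(sx, sy)
    cx, cy = center
    if cx == 0 and cy == 0:
        return core
    return translation_matrix(cx, cy) @ core @ translation_matrix(-cx, -cy)


def transform_points(points: np.ndarray, transform: AffineTransform) -> np.ndarray:
    """Push (n, 2) points through the homogeneous matrix."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ones = np.ones((pts.shape[0], 1))
    out = np.hstack([pts, ones]) @ transform.matrix.T
    return out[:, :2]


def warp_image(
    img: GrayImage,
    transform: AffineTransform,
    interpolation: str = "bilinear",
) -> GrayImage:
    """Resample an image under an affine map by inverse mapping.

    Output has the input's dimensions; regions mapped from outside the frame
    are filled with 0 (black, the radiograph background). ``interpolation``
    is ``"bilinear"`` for intensity images or ``"nearest"`` for masks, where
    averaging would smear labels.
    """
    orders = {"bilinear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    # skimage's transform classes use (x, y) = (col, row) coordinates, same
    # convention as ours, so the matrix passes through directly.
    inv = _SkAffine(matrix=np.linalg.inv(transform.matrix))
    out = _sk_warp(
        np.asarray(img.pixels, dtype=float),
        inverse_map=inv,
        order=orders[interpolation],
        cval=0.0,
        preserve_range=True,
        clip=True,
    )
    return GrayImage(out, scale=img.scale)


def transform_polygon(
    annotation: PolygonAnnotation,
    transform: AffineTransform,
    width: int,
    height: int,
    min_area: float = 10.0,
) -> PolygonAnnotation | None:
    """Transform a normalized polygon and clip it to the image rectangle.

    Vertices are denormalized, mapped through the affine, intersected with
    the frame, and re-normalized. Returns ``None`` when the clipped region
    has fewer than 3 vertices or area below ``min_area`` pixels² — dropping
    is a result, not an error. When clipping splits the polygon, the largest
    piece is kept.
    """
    pts = transform_points(denormalize_coords(annotation, width, height), transform)
    poly = sgeom.Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    clipped = poly.intersection(sgeom.box(0.0, 0.0, float(width), float(height)))
    if clipped.is_empty:
        return None
    if clipped.geom_type == "MultiPolygon":
        clipped = max(clipped.geoms, key=lambda g: g.area)
    if clipped.geom_type != "Polygon" or clipped.area < min_area:
        return None
    if poly.geom_type == "Polygon" and abs(clipped.area - poly.area) < 1e-9:
        # nothing was cut away: keep the mapped vertices and their order
        coords = pts
    else:
        coords = np.asarray(clipped.exterior.coords[:-1], dtype=float)
    if coords.shape[0] < 3:
        return None
    return annotation.with_vertices(normalize_coords(coords, width, height))


def polygon_area(points: np.ndarray) -> float:
    """Unsigned polygon area by the shoelace formula."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rasterize_polygon(points: np.ndarray, width: int, height: int) -> np.ndarray:
    """Boolean mask of the polygon's interior on a ``height``×``width`` grid.

    ``points`` are absolute (x, y) pixel coordinates.
    """
    pts = np.asarray(points, dtype=float)
    mask = np.zeros((height, width), dtype=bool)
    rr, cc = _draw_polygon(pts[:, 1], pts[:, 0], shape=(height, width))
    mask[rr, cc] = True
    return mask


def spatial_loss(
    targets: np.ndarray,
    sources: np.ndarray,
    transform: AffineTransform,
    lam: float = 0.01,
) -> float:
    """Spatial-distortion diagnostic for a fitted/constructed transform.

    ``Σ_i ‖P̂_i − T(P_i)‖² + λ·‖T‖_F`` where P̂ are target points, T(P) the
    transformed source points, and ‖·‖_F the (unsquared) Frobenius norm of
    the 3×3 matrix. λ defaults to 0.01. Exposed as a validation metric; no
    optimizer is attached to it.
    """
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    s = np.atleast_2d(np.asarray(sources, dtype=float))
    if t.shape != s.shape or t.shape[0] < 1:
        raise ValueError("targets and sources must have equal, nonzero length")
    residual = t - transform_points(s, transform)
    return float(np.sum(residual**2) + lam * np.linalg.norm(transform.matrix, "fro"))
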