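"""Affine construction, point/pixel/polygon transforms, spatial loss."""

import math

import numpy as np
import pytest
import shapely.geometry as sgeom

from cxraug.formats import GrayImage, PolygonAnnotation, denormalize_coords
from cxraug.geometry import (
    AffineTransform,
    compose_affine,
    polygon_area,
    rasterize_polygon,
    rotation_matrix,
    scale_matrix,
    spatial_loss,
    transform_points,
    transform_polygon,
    warp_image,
)


class TestRotation:
    def test_zero_is_identity(self):
        assert np.allclose(rotation_matrix(0).matrix, np.eye(3))

    def test_quarter_turn(self):
        assert np.allclose(transform_points([[1, 0]], rotation_matrix(90)), [[0, 1]], atol=1e-12)

    def test_five_degrees(self):
        out = transform_points([[1, 0]], rotation_matrix(5))
        assert np.allclose(out, [[0.996195, 0.087156]], atol=1e-6)

    def test_orthonormal_unit_determinant(self):
        t = rotation_matrix(37.3)
        lin = t.matrix[:2, :2]
        assert np.allclose(lin @ lin.T, np.eye(2), atol=1e-12)
        assert math.isclose(t.det, 1.0, abs_tol=1e-12)


class TestScale:
    def test_unit_is_identity(self):
        assert np.allclose(scale_matrix(1, 1).matrix, np.eye(3))

    def test_componentwise(self):
        assert np.allclose(transform_points([[3, 4]], scale_matrix(2, 0.5)), [[6, 2]])

    def test_area_scaling_via_determinant(self):
        assert math.isclose(scale_matrix(0.95, 0.95).det, 0.9025, rel_tol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            scale_matrix(0, 1)


class TestCompose:
    def test_identity(self):
        t = compose_affine(center=(123.0, 45.0))
        assert np.allclose(t.matrix, np.eye(3), atol=1e-12)

    def test_matrix_product_example(self):
        # scale 2, then translate (3, 0): (1,1) -> (5, 2)
        t = compose_affine(theta=0, tx=3, ty=0, sx=2, sy=2)
        assert np.allclose(transform_points([[1, 1]], t), [[5, 2]])

    def test_center_is_fixed_point(self):
        t = compose_affine(theta=90, center=(400, 400))
        assert np.allclose(transform_points([[400, 400]], t), [[400, 400]], atol=1e-9)

    def test_equals_sequential_application(self, rng):
        theta, tx, ty, sx, sy = 7.0, 12.0, -4.0, 1.03, 0.97
        t = compose_affine(theta, tx, ty, sx, sy)
        pts = rng.uniform(-100, 100, (20, 2))
        seq = transform_points(pts, scale_matrix(sx, sy))
        seq = transform_points(seq, rotation_matrix(theta))
        seq = seq + [tx, ty]
        assert np.abs(transform_points(pts, t) - seq).max() < 1e-9


class TestTransformPoints:
    def test_identity(self, rng):
        pts = rng.uniform(0, 800, (10, 2))
        assert np.allclose(transform_points(pts, AffineTransform.identity()), pts)

    def test_inverse_consistency(self, rng):
        t = compose_affine(theta=10, tx=5, ty=-3, sx=1.05, sy=0.95, center=(400, 400))
        pts = rng.uniform(0, 800, (50, 2))
        back = transform_points(transform_points(pts, t), t.inverse())
        assert np.abs(back - pts).max() < 1e-9

    def test_rotation_about_point(self):
        t = compose_affine(theta=90, center=(1, 1))
        assert np.allclose(transform_points([[2, 1]], t), [[1, 2]], atol=1e-12)


class TestWarpImage:
    def test_identity(self, rng):
        img = GrayImage(rng.uniform(0, 1, (64, 64)), scale="unit")
        out = warp_image(img, AffineTransform.identity())
        assert np.allclose(out.pixels, img.pixels, atol=1e-12)

    def test_four_quarter_turns_recover_image(self, rng):
        img = GrayImage(rng.uniform(0, 1, (101, 101)), scale="unit")
        t = compose_affine(theta=90, center=(50, 50))
        out = img
        for _ in range(4):
            out = warp_image(out, t)
        assert np.mean(np.abs(out.pixels - img.pixels)) < 0.02

    def test_constant_inside_frame(self):
        img = GrayImage(np.full((100, 100), 0.6), scale="unit")
        t = compose_affine(theta=5, center=(50, 50))
        out = warp_image(img, t)
        interior = out.pixels[30:70, 30:70]
        assert np.allclose(interior, 0.6, atol=1e-9)


class TestTransformPolygon:
    square = PolygonAnnotation(2, np.array([[0.4, 0.4], [0.6, 0.4], [0.6, 0.6], [0.4, 0.6]]))

    def test_identity_unchanged(self):
        out = transform_polygon(self.square, AffineTransform.identity(), 800, 800)
        assert out.class_id == 2
        ring_a = sgeom.Polygon(out.vertices)
        ring_b = sgeom.Polygon(self.square.vertices)
        assert ring_a.symmetric_difference(ring_b).area < 1e-9

    def test_pushed_fully_outside_is_dropped(self):
        t = compose_affine(tx=2000, ty=0)
        assert transform_polygon(self.square, t, 800, 800) is None

    def test_half_shifted_square_clips_to_half_area(self):
        # square spans x: 320..480 px; shift so half of it leaves the frame
        t = compose_affine(tx=400.0)  # now spans 720..880, frame ends at 800
        out = transform_polygon(self.square, t, 800, 800)
        area = polygon_area(denormalize_coords(out, 800, 800))
        assert math.isclose(area, 0.5 * 160 * 160, rel_tol=1e-6)

    def test_area_scales_with_determinant(self, rng):
        t = compose_affine(theta=8, sx=1.04, sy=0.96, center=(400, 400))
        pts = denormalize_coords(self.square, 800, 800)
        transformed = np.asarray(
            sgeom.Polygon(pts).exterior.coords[:-1]
        )  # original ring
        out_pts = transform_points(transformed, t)
        assert math.isclose(
            polygon_area(out_pts), abs(t.det) * polygon_area(transformed), rel_tol=1e-6
        )


class TestMaskPolygonAlignment:
    def test_alignment_iou(self, phantom, rng):
        """The warped rasterized mask and the rasterized transformed polygon
        must agree (IoU >= 0.95) — the pipeline's central alignment claim."""
        t = compose_affine(theta=10, tx=14, ty=-10, sx=1.05, sy=1.05, center=(400, 400))
        for ann in phantom.annotations:
            mask = rasterize_polygon(denormalize_coords(ann, 800, 800), 800, 800)
            if mask.sum() < 500:
                continue
            warped = (
                warp_image(GrayImage(mask.astype(float), scale="unit"), t, "nearest").pixels
                > 0.5
            )
            out = transform_polygon(ann, t, 800, 800)
            poly_mask = rasterize_polygon(denormalize_coords(out, 800, 800), 800, 800)
            union = np.count_nonzero(poly_mask | warped)
            assert np.count_nonzero(poly_mask & warped) / union >= 0.95


class TestSpatialLoss:
    def test_perfect_alignment_zero(self, rng):
        t = compose_affine(theta=5, tx=2, ty=1, sx=1.02, sy=1.02)
        pts = rng.uniform(0, 800, (10, 2))
        assert spatial_loss(transform_points(pts, t), pts, t, lam=0.0) == 0.0

    def test_identity_regularizer_only(self):
        pts = np.array([[1.0, 2.0]])
        val = spatial_loss(pts, pts, AffineTransform.identity(), lam=0.01)
        assert math.isclose(val, 0.01 * math.sqrt(3), rel_tol=1e-12)

    def test_unit_residual(self):
        val = spatial_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]]),
                           AffineTransform.identity(), lam=0.0)
        assert val == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spatial_loss(np.zeros((2, 2)), np.zeros((3, 2)), AffineTransform.identity())
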