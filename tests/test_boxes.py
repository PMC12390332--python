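"""Box geometry and IoU-family losses: worked examples against
independent oracles, plus the analytic invariants of the SIoU terms."""

import numpy as np
import pytest

from fbstrnet import boxes
from fbstrnet.boxes import BoxCXCYWH, BoxXYXY


def raster_iou(a, b, n=800):
    """Rasterization oracle: count membership on a fine pixel grid."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    lo = np.minimum(a[:2], b[:2]) - 1
    hi = np.maximum(a[2:], b[2:]) + 1
    xs = np.linspace(lo[0], hi[0], n)
    ys = np.linspace(lo[1], hi[1], n)
    xx, yy = np.meshgrid(xs, ys)

    def inside(box):
        return (xx >= box[0]) & (xx <= box[2]) & (yy >= box[1]) & (yy <= box[3])

    ia, ib = inside(a), inside(b)
    union = (ia | ib).sum()
    return (ia & ib).sum() / union if union else 0.0


class TestIoU:
    def test_identity(self):
        assert boxes.iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint(self):
        assert boxes.iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_partial_overlap_matches_raster_oracle(self):
        assert boxes.iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7, abs=1e-9)
        assert raster_iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7, abs=5e-3)

    def test_random_pairs_match_raster_oracle(self, rng):
        for _ in range(20):
            a = np.sort(rng.uniform(0, 10, 4).reshape(2, 2), axis=0).T.ravel()[[0, 2, 1, 3]]
            b = np.sort(rng.uniform(0, 10, 4).reshape(2, 2), axis=0).T.ravel()[[0, 2, 1, 3]]
            a = [min(a[0], a[2]), min(a[1], a[3]), max(a[0], a[2]), max(a[1], a[3])]
            b = [min(b[0], b[2]), min(b[1], b[3]), max(b[0], b[2]), max(b[1], b[3])]
            assert boxes.iou(a, b) == pytest.approx(raster_iou(a, b), abs=5e-3)

    def test_degenerate_boxes_yield_zero(self):
        assert boxes.iou((1, 1, 1, 1), (0, 0, 2, 2)) == 0.0
        assert boxes.iou((1, 1, 1, 1), (1, 1, 1, 1)) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            boxes.iou((0, 0, np.nan, 1), (0, 0, 1, 1))
        with pytest.raises(ValueError):
            boxes.iou((0, 0, np.inf, 1), (0, 0, 1, 1))


class TestAngleTerm:
    def test_horizontal_offset_is_zero(self):
        assert boxes.angle_loss((1, 1, 2, 2), (3, 1, 2, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_offset_is_one(self):
        # arcsin(1/sqrt(2)) = pi/4 exactly cancels the phase shift
        assert boxes.angle_loss((1, 1, 2, 2), (2, 2, 2, 2)) == pytest.approx(1.0, abs=1e-12)

    def test_coincident_centers_zero_by_convention(self):
        assert boxes.angle_loss((1, 1, 2, 2), (1, 1, 4, 4)) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(200):
            g = BoxCXCYWH(*rng.uniform(1, 9, 2), *rng.uniform(0.5, 3, 2))
            p = BoxCXCYWH(*rng.uniform(1, 9, 2), *rng.uniform(0.5, 3, 2))
            assert boxes.angle_loss(g, p) == pytest.approx(boxes.angle_loss(p, g), abs=1e-12)

    def test_zeros_on_axes_maxima_at_diagonals(self):
        """Scan 360 directions: term vanishes on axis alignment and peaks at 45 deg."""
        phis = np.deg2rad(np.arange(360))
        lam = np.array([
            boxes.angle_loss((5, 5, 2, 2), (5 + 3 * np.cos(p), 5 + 3 * np.sin(p), 2, 2))
            for p in phis
        ])
        axes_deg = [0, 90, 180, 270]
        diag_deg = [45, 135, 225, 315]
        assert np.allclose(lam[axes_deg], 0.0, atol=1e-9)
        assert np.allclose(lam[diag_deg], 1.0, atol=1e-9)
        assert np.all(lam >= -1e-12) and np.all(lam <= 1 + 1e-12)
        assert np.argmax(lam[:91]) == 45


class TestDistanceTerm:
    def test_identical_boxes_zero(self):
        assert boxes.distance_loss((1, 1, 2, 2), (1, 1, 2, 2), 0.0) == pytest.approx(0.0)

    def test_horizontal_example(self):
        # gamma=2, rho_x=(2/4)^2, rho_y=0 -> 1 - e^{-0.5}
        got = boxes.distance_loss((1, 1, 2, 2), (3, 1, 2, 2), 0.0)
        assert got == pytest.approx(1 - np.exp(-0.5), abs=1e-9)

    def test_diagonal_example(self):
        # gamma=1, rho_x=rho_y=(1/4)^2 -> 2(1 - e^{-1/16})
        got = boxes.distance_loss((1, 1, 2, 2), (2, 2, 4, 4), 1.0)
        assert got == pytest.approx(2 * (1 - np.exp(-0.0625)), abs=1e-9)


class TestShapeTerm:
    def test_equal_shapes_zero_anywhere(self):
        assert boxes.shape_loss((0, 0, 3, 2), (9, 9, 3, 2), 4) == pytest.approx(0.0)

    def test_double_size_example(self):
        got = boxes.shape_loss((1, 1, 2, 2), (5, 5, 4, 4), 4)
        assert got == pytest.approx(2 * (1 - np.exp(-0.5)) ** 4, abs=1e-6)

    def test_one_dimension_example(self):
        got = boxes.shape_loss((1, 1, 2, 2), (5, 5, 2, 4), 4)
        assert got == pytest.approx((1 - np.exp(-0.5)) ** 4, abs=1e-6)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            boxes.shape_loss((0, 0, 2, 2), (0, 0, 2, 2), theta=0)


def scalar_siou(g, p, theta=4.0):
    """Independent scalar re-derivation of the SIoU composition."""
    import math

    gx1, gy1, gx2, gy2 = g
    px1, py1, px2, py2 = p
    iw = max(min(gx2, px2) - max(gx1, px1), 0.0)
    ih = max(min(gy2, py2) - max(gy1, py1), 0.0)
    inter = iw * ih
    union = (gx2 - gx1) * (gy2 - gy1) + (px2 - px1) * (py2 - py1) - inter
    iou_v = inter / union if union else 0.0
    gcx, gcy = (gx1 + gx2) / 2, (gy1 + gy2) / 2
    pcx, pcy = (px1 + px2) / 2, (py1 + py2) / 2
    sigma = math.hypot(gcx - pcx, gcy - pcy)
    lam = 0.0
    if sigma > 0:
        lam = 1 - 2 * math.sin(math.asin(min(abs(gcy - pcy) / sigma, 1.0)) - math.pi / 4) ** 2
    cw = max(gx2, px2) - min(gx1, px1)
    ch = max(gy2, py2) - min(gy1, py1)
    gamma = 2 - lam
    delta = (1 - math.exp(-gamma * ((gcx - pcx) / cw) ** 2)) + (
        1 - math.exp(-gamma * ((gcy - pcy) / ch) ** 2)
    )
    gw, gh, pw, ph = gx2 - gx1, gy2 - gy1, px2 - px1, py2 - py1
    omega = (1 - math.exp(-abs(pw - gw) / max(pw, gw))) ** theta + (
        1 - math.exp(-abs(ph - gh) / max(ph, gh))
    ) ** theta
    return 1 - iou_v + (delta + omega) / 2


class TestSIoU:
    def test_perfect_match_zero(self):
        assert boxes.siou_loss((0, 0, 2, 2), (0, 0, 2, 2)).loss == pytest.approx(0.0, abs=1e-9)

    def test_adjacent_boxes_composite(self):
        t = boxes.siou_loss((0, 0, 2, 2), (2, 0, 4, 2), theta=4)
        assert t.loss == pytest.approx(1.196735, abs=1e-5)
        assert t.loss == pytest.approx(scalar_siou((0, 0, 2, 2), (2, 0, 4, 2)), abs=1e-9)
        assert t.iou == 0.0 and t.lambda_angle == pytest.approx(0.0, abs=1e-12)

    def test_nested_boxes_composite(self):
        t = boxes.siou_loss((0, 0, 2, 2), (0, 0, 4, 4), theta=4)
        assert t.loss == pytest.approx(0.834555, abs=1e-5)
        assert t.loss == pytest.approx(scalar_siou((0, 0, 2, 2), (0, 0, 4, 4)), abs=1e-9)
        assert t.iou == pytest.approx(0.25, abs=1e-9)
        assert t.lambda_angle == pytest.approx(1.0, abs=1e-9)

    def test_matches_scalar_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            g = np.sort(rng.uniform(0, 20, (2, 2)), axis=0)
            p = np.sort(rng.uniform(0, 20, (2, 2)), axis=0)
            gb = (g[0, 0], g[0, 1], g[1, 0], g[1, 1])
            pb = (p[0, 0], p[0, 1], p[1, 0], p[1, 1])
            assert boxes.siou_loss(gb, pb).loss == pytest.approx(
                scalar_siou(gb, pb), abs=1e-8
            )

    def test_term_ranges(self, rng):
        g = np.sort(rng.uniform(0, 50, (10000, 2, 2)), axis=1).reshape(10000, 4)
        p = np.sort(rng.uniform(0, 50, (10000, 2, 2)), axis=1).reshape(10000, 4)
        t = boxes.siou_loss(g, p)
        assert np.all((t.iou >= 0) & (t.iou <= 1))
        assert np.all((t.lambda_angle >= -1e-12) & (t.lambda_angle <= 1 + 1e-12))
        assert np.all((t.gamma >= 1 - 1e-12) & (t.gamma <= 2 + 1e-12))
        assert np.all((t.delta >= 0) & (t.delta < 2))
        assert np.all((t.omega >= 0) & (t.omega < 2))
        assert np.all((t.loss >= -1e-12) & (t.loss < 3))

    def test_translation_and_scale_invariance(self, rng):
        """Lambda, delta, omega depend only on the relative configuration."""
        n = 10000
        g = np.sort(rng.uniform(0, 50, (n, 2, 2)), axis=1).reshape(n, 4)
        p = np.sort(rng.uniform(0, 50, (n, 2, 2)), axis=1).reshape(n, 4)
        shift = rng.uniform(-100, 100, (n, 2))
        scale = rng.uniform(0.1, 10, (n, 1))
        t0 = boxes.siou_loss(g, p)
        tt = boxes.siou_loss(g + np.tile(shift, 2), p + np.tile(shift, 2))
        ts = boxes.siou_loss(g * scale, p * scale)
        for term in ("iou", "lambda_angle", "delta", "omega", "loss"):
            np.testing.assert_allclose(getattr(tt, term), getattr(t0, term), atol=1e-7)
            np.testing.assert_allclose(getattr(ts, term), getattr(t0, term), atol=1e-6)

    def test_monotone_in_axis_aligned_separation(self):
        """Once disjoint, pushing equal boxes apart never lowers the loss."""
        d = np.linspace(2.0, 60.0, 200)
        losses = [boxes.siou_loss((0, 0, 2, 2), (x, 0, x + 2, 2)).loss for x in d]
        assert np.all(np.diff(losses) >= -1e-12)


def scalar_ciou(g, p):
    """Independent CIoU reference (standard published definition)."""
    import math

    gx1, gy1, gx2, gy2 = g
    px1, py1, px2, py2 = p
    iw = max(min(gx2, px2) - max(gx1, px1), 0.0)
    ih = max(min(gy2, py2) - max(gy1, py1), 0.0)
    inter = iw * ih
    union = (gx2 - gx1) * (gy2 - gy1) + (px2 - px1) * (py2 - py1) - inter
    iou_v = inter / union if union else 0.0
    cw = max(gx2, px2) - min(gx1, px1)
    ch = max(gy2, py2) - min(gy1, py1)
    rho2 = ((gx1 + gx2) / 2 - (px1 + px2) / 2) ** 2 + ((gy1 + gy2) / 2 - (py1 + py2) / 2) ** 2
    v = 4 / math.pi**2 * (
        math.atan((gx2 - gx1) / (gy2 - gy1)) - math.atan((px2 - px1) / (py2 - py1))
    ) ** 2
    alpha = v / (1 - iou_v + v) if (1 - iou_v + v) > 0 else 0.0
    return 1 - iou_v + rho2 / (cw**2 + ch**2) + alpha * v


class TestCIoU:
    def test_identical_boxes_zero(self):
        assert boxes.ciou_loss((0, 0, 2, 2), (0, 0, 2, 2)) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_exceeds_one_minus_iou(self):
        assert boxes.ciou_loss((0, 0, 2, 2), (10, 0, 12, 2)) > 1.0

    def test_matches_independent_reference(self, rng):
        for _ in range(300):
            g = np.sort(rng.uniform(0.5, 20, (2, 2)), axis=0)
            p = np.sort(rng.uniform(0.5, 20, (2, 2)), axis=0)
            gb = (g[0, 0], g[0, 1], g[1, 0] + 0.1, g[1, 1] + 0.1)
            pb = (p[0, 0], p[0, 1], p[1, 0] + 0.1, p[1, 1] + 0.1)
            assert boxes.ciou_loss(gb, pb) == pytest.approx(scalar_ciou(gb, pb), abs=1e-6)


class TestBoxForms:
    def test_roundtrip(self, rng):
        for _ in range(100):
            a = np.sort(rng.uniform(0, 10, (2, 2)), axis=0)
            b = BoxXYXY(a[0, 0], a[0, 1], a[1, 0], a[1, 1])
            r = b.to_cxcywh().to_xyxy()
            assert np.allclose(b.as_array(), r.as_array(), atol=1e-12)

    def test_invalid_corners_rejected(self):
        with pytest.raises(ValueError):
            BoxXYXY(2, 0, 1, 1)
        with pytest.raises(ValueError):
            BoxCXCYWH(0, 0, -1, 1)
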