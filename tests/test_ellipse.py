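import json
import math

import numpy as np
import pytest

from penseg.ellipse import (
    AnnotationSet,
    AnnotationParseError,
    Ellipse,
    FitError,
    InvalidEllipseError,
    ellipse_halves,
    fit_ellipse,
    mask_iou,
    rasterize_ellipse,
    read_annotations,
    scale_ellipse,
    write_annotations,
)

from conftest import brute_force_mask, random_ellipse


class TestEllipseType:
    def test_axis_invariant(self):
        with pytest.raises(InvalidEllipseError):
            Ellipse(cx=0, cy=0, a=2, b=3, phi=0)
        with pytest.raises(InvalidEllipseError):
            Ellipse(cx=0, cy=0, a=2, b=0, phi=0)

    def test_phi_wraps_into_range(self):
        assert Ellipse(cx=0, cy=0, a=2, b=1, phi=370.0).phi == pytest.approx(10.0)

    def test_depth_ranks_unique_per_image(self):
        es = [Ellipse(cx=5, cy=5, a=2, b=1, phi=0, depth=0) for _ in range(2)]
        with pytest.raises(InvalidEllipseError):
            AnnotationSet(image_id="x", image_size=(11, 11), ellipses=es)

    def test_center_must_be_near_frame(self):
        e = Ellipse(cx=-50, cy=5, a=3, b=2, phi=0)
        with pytest.raises(InvalidEllipseError):
            AnnotationSet(image_id="x", image_size=(11, 11), ellipses=[e])


class TestRasterize:
    def test_circle_pixel_count_matches_enumeration(self):
        e = Ellipse(cx=5, cy=5, a=2, b=2, phi=0)
        mask = rasterize_ellipse(e, (11, 11))
        # brute force: integer centers with dx^2 + dy^2 <= 4
        expected = sum(
            1 for r in range(11) for c in range(11) if (c - 5) ** 2 + (r - 5) ** 2 <= 4
        )
        assert expected == 13
        assert mask.sum() == expected

    def test_outside_frame_is_empty(self):
        e = Ellipse(cx=-100, cy=-100, a=2, b=2, phi=0)
        assert not rasterize_ellipse(e, (11, 11)).any()

    def test_central_symmetry_phi_plus_180(self, rng):
        for _ in range(10):
            e = random_ellipse(rng)
            m1 = rasterize_ellipse(e, (96, 96))
            m2 = rasterize_ellipse(e.flipped(), (96, 96))
            assert (m1 == m2).all()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            e = random_ellipse(rng, frame=40, a_range=(4.0, 12.0))
            assert (rasterize_ellipse(e, (40, 40)) == brute_force_mask(e, (40, 40))).all()

    def test_area_approaches_continuous_area(self, rng):
        for _ in range(10):
            e = random_ellipse(rng, a_range=(8.0, 28.0))
            if e.b < 8:
                e = scale_ellipse(e, 8.0 / e.b)
            if max(e.a, e.b) > 28:
                continue
            n = rasterize_ellipse(e, (128, 128)).sum()
            assert abs(n - e.area) / e.area < 0.05

    def test_monotone_under_scaling(self, rng):
        e = random_ellipse(rng)
        m_small = rasterize_ellipse(scale_ellipse(e, 0.5), (96, 96))
        m_big = rasterize_ellipse(e, (96, 96))
        assert not (m_small & ~m_big).any()


class TestScale:
    def test_halving_axes(self):
        e = Ellipse(cx=1, cy=2, a=10, b=4, phi=33, oriented=True, depth=3)
        s = scale_ellipse(e, 0.5)
        assert (s.a, s.b) == (5, 2)
        assert (s.cx, s.cy, s.phi, s.oriented, s.depth) == (1, 2, 33, True, 3)

    def test_identity_and_inverse(self):
        e = Ellipse(cx=0, cy=0, a=7, b=3, phi=10)
        assert scale_ellipse(e, 1.0) == e
        back = scale_ellipse(scale_ellipse(e, 0.5), 2.0)
        assert back.a == pytest.approx(e.a) and back.b == pytest.approx(e.b)

    @pytest.mark.parametrize("factor", [0.0, -1.0])
    def test_invalid_factor(self, factor):
        with pytest.raises(ValueError):
            scale_ellipse(Ellipse(cx=0, cy=0, a=2, b=1, phi=0), factor)


class TestFit:
    def test_round_trip_recovery(self):
        e = Ellipse(cx=20, cy=15, a=10, b=4, phi=30)
        fit = fit_ellipse(np.argwhere(rasterize_ellipse(e, (64, 64))))
        assert math.hypot(fit.cx - e.cx, fit.cy - e.cy) <= 0.5
        assert abs(fit.a - e.a) / e.a <= 0.05
        assert abs(fit.b - e.b) / e.b <= 0.05
        assert abs((fit.phi - e.phi + 90) % 180 - 90) <= 2.0
        assert not fit.oriented

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_ellipse([(0, 0), (0, 5), (5, 0), (5, 5)])

    def test_collinear_points(self):
        with pytest.raises(FitError):
            fit_ellipse([(i, 2 * i) for i in range(10)])

    def test_circle_axes_nearly_equal(self):
        e = Ellipse(cx=30, cy=30, a=10, b=10, phi=0)
        fit = fit_ellipse(np.argwhere(rasterize_ellipse(e, (64, 64))))
        assert abs(fit.a - fit.b) / fit.a < 0.02


class TestMaskIoU:
    def test_identical_nonempty(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        assert mask_iou(m, m) == 1.0

    def test_disjoint_and_empty(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        assert mask_iou(a, b) == 0.0
        assert mask_iou(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 0.0

    def test_partial_overlap_count(self):
        a = np.zeros((4, 8), bool)
        b = np.zeros((4, 8), bool)
        a[0, :8] = True  # |A| = 8
        b[1, :4] = True
        b[0, :4] = True  # |B| = 8, inter = 4, union = 12
        assert mask_iou(a, b) == pytest.approx(4 / 12)
        assert mask_iou(b, a) == pytest.approx(mask_iou(a, b))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((3, 3), bool), np.zeros((4, 3), bool))


class TestHalves:
    def test_exact_partition(self, rng):
        for _ in range(10):
            e = random_ellipse(rng, oriented=True)
            full = rasterize_ellipse(e, (96, 96))
            front, back = ellipse_halves(e, (96, 96))
            assert not (front & back).any()
            assert ((front | back) == full).all()

    def test_flip_swaps_halves(self):
        e = Ellipse(cx=20, cy=20, a=8, b=4, phi=0, oriented=True)
        f0, b0 = ellipse_halves(e, (40, 40))
        f1, b1 = ellipse_halves(e.flipped(), (40, 40))
        # the on-line pixels (x'=0) stay in the front of both orientations
        line = f0 & f1
        assert (f1 == (b0 | line)).all()

    def test_circle_counts_with_tie_rule(self):
        # circle a=b=2 at (5,5), phi=0: enumerate dx^2+dy^2 <= 4 pixels;
        # front = dx >= 0 (ties toward front)
        e = Ellipse(cx=5, cy=5, a=2, b=2, phi=0, oriented=True)
        front, back = ellipse_halves(e, (11, 11))
        expected_front = sum(
            1
            for r in range(11)
            for c in range(11)
            if (c - 5) ** 2 + (r - 5) ** 2 <= 4 and c - 5 >= 0
        )
        assert front.sum() == expected_front  # 4 strict + 5 on the dividing line
        assert front.sum() + back.sum() == 13


class TestAnnotationIO:
    def _sample_sets(self):
        return [
            AnnotationSet(
                image_id="img0",
                image_size=(64, 48),
                ellipses=[
                    Ellipse(cx=10.25, cy=20.5, a=8.125, b=3.0625, phi=123.456,
                            oriented=True, depth=1),
                    Ellipse(cx=30, cy=30, a=5, b=2, phi=0.0, oriented=False, depth=0),
                ],
            ),
            AnnotationSet(image_id="img1", image_size=(32, 32), ellipses=[]),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "ann.json"
        sets = self._sample_sets()
        write_annotations(sets, path)
        back = read_annotations(path)
        assert len(back) == 2
        for orig, re in zip(sets, back):
            assert re.image_id == orig.image_id
            assert re.image_size == orig.image_size
            for a, b in zip(orig.ellipses, re.ellipses):
                for f in ("cx", "cy", "a", "b", "phi"):
                    assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-9)
                assert (a.oriented, a.depth) == (b.oriented, b.depth)

    def test_missing_field_names_offender(self, tmp_path):
        path = tmp_path / "bad.json"
        payload = [
            {
                "image_id": "imgX",
                "height": 8,
                "width": 8,
                "ellipses": [{"cx": 1, "cy": 1, "b": 1, "phi": 0, "oriented": False, "depth": 0}],
            }
        ]
        path.write_text(json.dumps(payload))
        with pytest.raises(AnnotationParseError, match="imgX.*'a'"):
            read_annotations(path)

    def test_empty_list(self, tmp_path):
        path = tmp_path / "empty.json"
        write_annotations([], path)
        assert read_annotations(path) == []
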