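import numpy as np
import pytest

from penseg.ellipse import AnnotationSet, Ellipse, mask_iou, rasterize_ellipse, scale_ellipse
from penseg.labels import (
    refit_ground_truth,
    render_all,
    render_bodypart,
    render_categorical,
    render_instance_map,
)

from conftest import random_ellipse


def two_overlapping(depth_top=0):
    e_top = Ellipse(cx=24, cy=24, a=10, b=5, phi=0, oriented=True, depth=depth_top)
    e_bot = Ellipse(cx=34, cy=26, a=10, b=5, phi=20, oriented=True, depth=1 - depth_top)
    return AnnotationSet(image_id="pair", image_size=(64, 64), ellipses=[e_top, e_bot])


class TestInstanceMap:
    def test_topmost_wins_in_overlap(self):
        ann = two_overlapping(depth_top=0)
        inst = render_instance_map(ann)
        m0 = rasterize_ellipse(ann.ellipses[0], ann.image_size)
        m1 = rasterize_ellipse(ann.ellipses[1], ann.image_size)
        inter = m0 & m1
        assert inter.any()
        assert (inst[inter] == 1).all()  # id 1 = first ellipse, depth 0
        assert (inst[m1 & ~inter] == 2).all()

    def test_disjoint_ids(self):
        es = [
            Ellipse(cx=12, cy=12, a=6, b=3, phi=0, depth=0),
            Ellipse(cx=40, cy=40, a=6, b=3, phi=90, depth=1),
        ]
        ann = AnnotationSet(image_id="d", image_size=(64, 64), ellipses=es)
        inst = render_instance_map(ann)
        for i, e in enumerate(es, start=1):
            m = rasterize_ellipse(e, ann.image_size)
            assert (inst[m] == i).all()

    def test_empty_annotation(self):
        ann = AnnotationSet(image_id="e", image_size=(16, 16), ellipses=[])
        assert not render_instance_map(ann).any()

    def test_depth_consistency_and_union(self, rng):
        # overlapping stack: the winning id must always be the min depth rank
        es = [
            Ellipse(cx=20 + 6 * i, cy=24, a=9, b=5, phi=15 * i, oriented=True, depth=d)
            for i, d in enumerate([2, 0, 1])
        ]
        ann = AnnotationSet(image_id="stack", image_size=(56, 72), ellipses=es)
        inst = render_instance_map(ann)
        masks = [rasterize_ellipse(e, ann.image_size) for e in es]
        union = np.zeros(ann.image_size, bool)
        for r, c in np.argwhere(sum(m.astype(int) for m in masks) > 0):
            covering = [i for i, m in enumerate(masks) if m[r, c]]
            best = min(covering, key=lambda i: es[i].depth)
            assert inst[r, c] == best + 1
        for m in masks:
            union |= m
        assert ((inst > 0) == union).all()

    def test_list_order_invariance(self):
        ann = two_overlapping()
        perm = AnnotationSet(
            image_id="pair", image_size=ann.image_size, ellipses=ann.ellipses[::-1]
        )
        a = render_instance_map(ann)
        b = render_instance_map(perm)
        # same partition; ids permuted along with the list
        assert ((a == 1) == (b == 2)).all() and ((a == 2) == (b == 1)).all()


class TestCategorical:
    def test_single_ellipse_core_is_scaled_rasterization(self):
        e = Ellipse(cx=24, cy=20, a=10, b=4, phi=30, depth=0)
        ann = AnnotationSet(image_id="s", image_size=(48, 48), ellipses=[e])
        cat = render_categorical(ann, core_scale=0.5)
        core = rasterize_ellipse(scale_ellipse(e, 0.5), ann.image_size)
        full = rasterize_ellipse(e, ann.image_size)
        assert ((cat == 2) == core).all()
        assert ((cat == 1) == (full & ~core)).all()

    def test_core_scale_near_one_leaves_thin_edge(self):
        e = Ellipse(cx=32, cy=32, a=20, b=12, phi=0, depth=0)
        ann = AnnotationSet(image_id="s", image_size=(64, 64), ellipses=[e])
        cat = render_categorical(ann, core_scale=0.999)
        assert (cat == 1).sum() <= 0.05 * (cat > 0).sum()

    def test_two_disjoint_animals_two_core_components(self):
        from skimage.measure import label

        es = [
            Ellipse(cx=14, cy=14, a=8, b=4, phi=0, depth=0),
            Ellipse(cx=44, cy=44, a=8, b=4, phi=90, depth=1),
        ]
        ann = AnnotationSet(image_id="two", image_size=(64, 64), ellipses=es)
        cat = render_categorical(ann, 0.5)
        _, n = label(cat == 2, connectivity=2, return_num=True)
        assert n == 2

    def test_invalid_core_scale(self):
        ann = AnnotationSet(image_id="x", image_size=(8, 8), ellipses=[])
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                render_categorical(ann, bad)

    def test_partition_of_foreground(self, rng):
        ann = two_overlapping()
        cat = render_categorical(ann)
        binary = render_instance_map(ann) > 0
        assert ((cat > 0) == binary).all()


class TestBodypart:
    def test_half_fraction_equals_front_half(self):
        from penseg.ellipse import ellipse_halves

        e = Ellipse(cx=24, cy=24, a=10, b=5, phi=25, oriented=True, depth=0)
        ann = AnnotationSet(image_id="h", image_size=(48, 48), ellipses=[e])
        bp = render_bodypart(ann, head_fraction=0.5)
        front, back = ellipse_halves(e, ann.image_size)
        assert ((bp == 2) == front).all()
        assert ((bp == 1) == back).all()

    def test_flip_swaps_head_cap(self):
        # non-integer center so no pixel sits exactly on the cap boundary
        e = Ellipse(cx=24.3, cy=23.6, a=10, b=5, phi=0, oriented=True, depth=0)
        ann_a = AnnotationSet(image_id="a", image_size=(48, 48), ellipses=[e])
        ann_b = AnnotationSet(image_id="b", image_size=(48, 48), ellipses=[e.flipped()])
        head_a = render_bodypart(ann_a, 0.4) == 2
        head_b = render_bodypart(ann_b, 0.4) == 2
        body = rasterize_ellipse(e, (48, 48))
        assert head_a.any() and head_b.any()
        assert not (head_a & head_b).any()
        # each cap is the enumeration of mask pixels beyond +/- x' = 2
        exp_a = body & (np.arange(48)[None, :] - 24.3 >= 2.0)
        exp_b = body & (24.3 - np.arange(48)[None, :] >= 2.0)
        assert (head_a == exp_a).all()
        assert (head_b == exp_b).all()

    def test_head_count_matches_enumeration(self):
        # axis-aligned: head pixels are mask pixels with x' >= a*(1-2f) = 2.0
        e = Ellipse(cx=24, cy=20, a=10, b=4, phi=0, oriented=True, depth=0)
        ann = AnnotationSet(image_id="c", image_size=(40, 48), ellipses=[e])
        bp = render_bodypart(ann, head_fraction=0.4)
        expected = sum(
            1
            for r in range(40)
            for c in range(48)
            if ((c - 24) / 10) ** 2 + ((r - 20) / 4) ** 2 <= 1 and (c - 24) >= 2.0
        )
        assert (bp == 2).sum() == expected

    def test_unoriented_rejected(self):
        e = Ellipse(cx=24, cy=24, a=10, b=5, phi=0, oriented=False, depth=0)
        ann = AnnotationSet(image_id="u", image_size=(48, 48), ellipses=[e])
        with pytest.raises(ValueError, match="oriented"):
            render_bodypart(ann)

    def test_partition_of_foreground(self):
        ann = two_overlapping()
        bp = render_bodypart(ann, 0.4)
        assert ((bp > 0) == (render_instance_map(ann) > 0)).all()


class TestRefit:
    def test_non_overlapping_matches_originals(self, rng):
        es = [
            Ellipse(cx=20, cy=20, a=10, b=4, phi=30, oriented=True, depth=0),
            Ellipse(cx=60, cy=60, a=12, b=6, phi=200, oriented=True, depth=1),
        ]
        ann = AnnotationSet(image_id="free", image_size=(96, 96), ellipses=es)
        adjusted, dropped = refit_ground_truth(ann)
        assert dropped == []
        for src, fit in zip(es, adjusted):
            assert abs(fit.cx - src.cx) <= 0.5 and abs(fit.cy - src.cy) <= 0.5
            assert abs(fit.a - src.a) / src.a <= 0.05
            assert abs((fit.phi - src.phi + 180) % 360 - 180) <= 2.0
            assert fit.oriented and fit.depth == src.depth

    @pytest.mark.parametrize(
        "top_cx, min_iou",
        [
            (26, 0.80),  # ~half the body hidden behind a round neighbour
            (30, 0.75),  # ~60% hidden: a convex fit cannot hug the cut much closer
        ],
    )
    def test_partially_occluded_fits_visible_region(self, top_cx, min_iou):
        bottom = Ellipse(cx=48, cy=40, a=16, b=8, phi=0, oriented=True, depth=1)
        top = Ellipse(cx=top_cx, cy=40, a=24, b=22, phi=90, oriented=True, depth=0)
        ann = AnnotationSet(image_id="occ", image_size=(80, 96), ellipses=[top, bottom])
        inst = render_instance_map(ann)
        adjusted, dropped = refit_ground_truth(ann)
        assert dropped == []
        visible = inst == 2
        fitted = rasterize_ellipse(adjusted[1], ann.image_size)
        assert mask_iou(fitted, visible) >= min_iou

    def test_fully_occluded_dropped(self):
        small = Ellipse(cx=32, cy=32, a=4, b=2, phi=0, oriented=True, depth=1)
        big = Ellipse(cx=32, cy=32, a=14, b=10, phi=0, oriented=True, depth=0)
        ann = AnnotationSet(image_id="gone", image_size=(64, 64), ellipses=[big, small])
        adjusted, dropped = refit_ground_truth(ann)
        assert dropped == [1]
        assert adjusted[1] is None and adjusted[0] is not None
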