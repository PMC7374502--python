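"""Render per-pixel training targets from ellipse annotations.

Four label maps are produced from one :class:`~penseg.ellipse.AnnotationSet`:

* ``instance``   — integer ids, 0 = background; where animals overlap, the
  one closest to the camera (smallest depth rank) overwrites the others;
* ``binary``     — foreground / background;
* ``categorical``— 0 background, 1 outer edge, 2 inner core, the inner core
  being the annotated ellipse with both semi-axes scaled down (a discrete
  distance-to-center encoding that keeps touching animals separable);
* ``bodypart``   — 0 background, 1 body, 2 head, the head being the
  elliptical cap in the direction of ``phi``.

Because painted ellipses only approximate the visible pixel sets once
occlusion is applied, the ground truth used for evaluation is *refit*: an
ellipse is fitted to each instance's visible pixels of the rendered map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ellipse import (
    AnnotationSet,
    Ellipse,
    FitError,
    _ellipse_frame,
    fit_ellipse,
    rasterize_ellipse,
    scale_ellipse,
)

__all__ = [
    "LabelMaps",
    "render_instance_map",
    "render_binary",
    "render_categorical",
    "render_bodypart",
    "render_all",
    "refit_ground_truth",
]

BACKGROUND, OUTER_EDGE, INNER_CORE = 0, 1, 2
BODY, HEAD = 1, 2


@dataclass
class LabelMaps:
    """All rendered per-pixel targets of one image."""

    instance: np.ndarray  # int32, 0 background, k>=1 instance id
    binary: np.ndarray  # uint8 {0,1}
    categorical: np.ndarray  # uint8 {0 bg, 1 edge, 2 core}
    bodypart: np.ndarray | None  # uint8 {0 bg, 1 body, 2 head}; None if unoriented


def render_instance_map(ann: AnnotationSet) -> np.ndarray:
    """Depth-ordered instance id map (topmost animal wins on overlaps)."""
    out = np.zeros(ann.image_size, dtype=np.int32)
    for idx, e in ann.by_depth(farthest_first=True):
        out[rasterize_ellipse(e, ann.image_size)] = idx
    return out


def render_binary(ann: AnnotationSet) -> np.ndarray:
    return (render_instance_map(ann) > 0).astype(np.uint8)


def render_categorical(ann: AnnotationSet, core_scale: float = 0.5) -> np.ndarray:
    """3-class distance encoding: background / outer edge / inner core.

    ``core_scale`` scales both semi-axes of the annotated ellipse (default
    0.5, i.e. the core covers 50% of each axis).  Overlaps are resolved by
    the same depth-ordered overwrite as the instance map: the topmost
    animal's edge may cover a lower animal's core.
    """
    if not (0.0 < core_scale < 1.0):
        raise ValueError(f"core_scale must be in (0, 1), got {core_scale}")
    out = np.zeros(ann.image_size, dtype=np.uint8)
    for _, e in ann.by_depth(farthest_first=True):
        out[rasterize_ellipse(e, ann.image_size)] = OUTER_EDGE
        out[rasterize_ellipse(scale_ellipse(e, core_scale), ann.image_size)] = INNER_CORE
    return out


def _head_mask(e: Ellipse, image_size, head_fraction: float) -> np.ndarray:
    # cap of the ellipse beyond x' = a*(1 - 2*head_fraction); ties toward the
    # head so head_fraction=0.5 reproduces the front half of ellipse_halves
    full = rasterize_ellipse(e, image_size)
    xp, _ = _ellipse_frame(e, image_size)
    return full & (xp >= e.a * (1.0 - 2.0 * head_fraction))


def render_bodypart(ann: AnnotationSet, head_fraction: float = 0.4) -> np.ndarray:
    """3-class body-part encoding: background / body / head.

    The head is the elliptical cap covering ``head_fraction`` of the
    major-axis extent on the side ``phi`` points to.  Requires every
    annotation to be oriented.
    """
    if not (0.0 < head_fraction < 1.0):
        raise ValueError(f"head_fraction must be in (0, 1), got {head_fraction}")
    out = np.zeros(ann.image_size, dtype=np.uint8)
    for _, e in ann.by_depth(farthest_first=True):
        if not e.oriented:
            raise ValueError(
                f"body-part labels need oriented ellipses; {ann.image_id!r} has an "
                f"unoriented one at depth {e.depth}"
            )
        out[rasterize_ellipse(e, ann.image_size)] = BODY
        out[_head_mask(e, ann.image_size, head_fraction)] = HEAD
    return out


def render_all(
    ann: AnnotationSet, core_scale: float = 0.5, head_fraction: float = 0.4
) -> LabelMaps:
    """Render every label map; body-part only when all ellipses are oriented."""
    instance = render_instance_map(ann)
    oriented = all(e.oriented for e in ann.ellipses)
    return LabelMaps(
        instance=instance,
        binary=(instance > 0).astype(np.uint8),
        categorical=render_categorical(ann, core_scale),
        bodypart=render_bodypart(ann, head_fraction) if oriented else None,
    )


def refit_ground_truth(
    ann: AnnotationSet,
) -> tuple[list[Ellipse | None], list[int]]:
    """Adjusted ground-truth ellipses fitted to the *visible* pixels.

    Returns ``(adjusted, dropped)`` where ``adjusted[i]`` corresponds to
    ``ann.ellipses[i]`` (``None`` when dropped) and ``dropped`` lists the
    0-based indices of instances with fewer than 5 visible pixels.  The
    orientation flag is copied from the source annotation, with the fitted
    axis direction snapped to within 90 degrees of the annotated ``phi``.
    """
    instance = render_instance_map(ann)
    adjusted: list[Ellipse | None] = []
    dropped: list[int] = []
    for i, src in enumerate(ann.ellipses):
        pixels = np.argwhere(instance == i + 1)
        fit = None
        if len(pixels) >= 5:
            try:
                fit = fit_ellipse(pixels)
            except FitError:
                fit = None
        if fit is None:
            dropped.append(i)
            adjusted.append(None)
            continue
        phi = fit.phi % 180.0
        if src.oriented:
            # pick the axis direction within 90 deg (circular) of the annotation
            if abs((phi - src.phi + 180.0) % 360.0 - 180.0) > 90.0:
                phi = (phi + 180.0) % 360.0
        adjusted.append(replace(fit, phi=phi, oriented=src.oriented, depth=src.depth))
    return adjusted, dropped
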