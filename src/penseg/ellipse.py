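"""Ellipse geometry, annotation data model and annotation file I/O.

The five-parameter ellipse (center, semi-axes, orientation) is the pose
representation used throughout the package: animals seen from above are
annotated as ellipses whose major axis points toward the head, and whose
integer depth rank records which animal lies on top where bodies overlap.

Conventions (used consistently everywhere):

* pixel coordinates are 0-based, ``x`` = column (right), ``y`` = row (down);
* a pixel belongs to an ellipse iff its *center* satisfies the closed
  interior inequality ``(x'/a)**2 + (y'/b)**2 <= 1``;
* ``phi`` is in degrees, measured from the +x axis toward +y, in [0, 360);
  for unoriented ellipses only ``phi mod 180`` is meaningful;
* semi-axes are normalized to ``a >= b`` (with a compensating 90-degree
  rotation where a fit returns them swapped).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.measure import EllipseModel, find_contours

__all__ = [
    "Ellipse",
    "AnnotationSet",
    "InvalidEllipseError",
    "FitError",
    "AnnotationParseError",
    "rasterize_ellipse",
    "scale_ellipse",
    "fit_ellipse",
    "mask_iou",
    "ellipse_halves",
    "read_annotations",
    "write_annotations",
]


class InvalidEllipseError(ValueError):
    """Ellipse parameters violate the type invariants."""


class FitError(RuntimeError):
    """Direct least-squares ellipse fit failed (too few or degenerate points)."""


class AnnotationParseError(ValueError):
    """An annotation file record is malformed."""


@dataclass(frozen=True)
class Ellipse:
    """Oriented ellipse pose of a single animal.

    Parameters
    ----------
    cx, cy:
        Center in pixel coordinates (continuous, 0-based, x right / y down).
    a, b:
        Semi-major and semi-minor axis lengths in pixels, ``a >= b > 0``.
    phi:
        Orientation in degrees, ``[0, 360)``.  When ``oriented`` is true the
        direction ``(cos phi, sin phi)`` points from the center toward the
        head end of the animal; otherwise only ``phi mod 180`` (the major
        axis) is meaningful.
    oriented:
        Whether the head direction of ``phi`` is meaningful.
    depth:
        Integer rank along the camera axis, 0 = closest to the camera
        (drawn on top).
    """

    cx: float
    cy: float
    a: float
    b: float
    phi: float
    oriented: bool = False
    depth: int = 0

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.a >= self.b):
            raise InvalidEllipseError(
                f"semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}"
            )
        if not (0.0 <= self.phi < 360.0):
            object.__setattr__(self, "phi", float(self.phi) % 360.0)
        if self.depth < 0:
            raise InvalidEllipseError(f"depth rank must be >= 0, got {self.depth}")

    @property
    def area(self) -> float:
        """Continuous area pi*a*b."""
        return math.pi * self.a * self.b

    def axis_direction(self) -> tuple[float, float]:
        """Unit vector along +phi (toward the head when oriented)."""
        r = math.radians(self.phi)
        return math.cos(r), math.sin(r)

    def flipped(self) -> "Ellipse":
        """Same ellipse with the head direction rotated by 180 degrees."""
        return replace(self, phi=(self.phi + 180.0) % 360.0)


@dataclass
class AnnotationSet:
    """All annotated animals of one image.

    Depth ranks must be unique within the set; ellipse ids used by the label
    renderer are 1-based indices into ``ellipses`` (list order, not depth).
    """

    image_id: str
    image_size: tuple[int, int]  # (height, width)
    ellipses: list[Ellipse] = field(default_factory=list)

    def __post_init__(self) -> None:
        depths = [e.depth for e in self.ellipses]
        if len(set(depths)) != len(depths):
            raise InvalidEllipseError(
                f"depth ranks must be unique in {self.image_id!r}, got {depths}"
            )
        h, w = self.image_size
        for e in self.ellipses:
            m = max(e.a, e.b)
            if not (-m <= e.cx <= w - 1 + m and -m <= e.cy <= h - 1 + m):
                raise InvalidEllipseError(
                    f"ellipse center ({e.cx}, {e.cy}) too far outside the "
                    f"{h}x{w} frame of {self.image_id!r}"
                )

    def by_depth(self, farthest_first: bool = True) -> list[tuple[int, Ellipse]]:
        """(1-based id, ellipse) pairs sorted by depth rank."""
        order = sorted(enumerate(self.ellipses, start=1), key=lambda t: t[1].depth)
        return order[::-1] if farthest_first else order


# ---------------------------------------------------------------------------
# geometry


def _ellipse_frame(e: Ellipse, image_size: tuple[int, int]):
    """Signed coordinates (x', y') of every pixel center in the ellipse frame."""
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - e.cx
    dy = yy - e.cy
    r = math.radians(e.phi)
    c, s = math.cos(r), math.sin(r)
    xp = dx * c + dy * s
    yp = -dx * s + dy * c
    return xp, yp


def rasterize_ellipse(e: Ellipse, image_size: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixel centers inside the closed ellipse interior."""
    h, w = image_size
    if h <= 0 or w <= 0:
        raise ValueError(f"image_size must be positive, got {image_size}")
    xp, yp = _ellipse_frame(e, image_size)
    return (xp / e.a) ** 2 + (yp / e.b) ** 2 <= 1.0


def scale_ellipse(e: Ellipse, factor: float) -> Ellipse:
    """Scale both semi-axes by ``factor``; pose otherwise unchanged."""
    if not factor > 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    return replace(e, a=e.a * factor, b=e.b * factor)


def mask_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two equal-shaped binary masks (0 if both empty)."""
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _moment_fit(pts: np.ndarray) -> tuple[float, float, float, float, float]:
    """Second-moment ellipse of a filled pixel set (exact for ideal fills)."""
    mu = pts.mean(axis=0)
    x = pts - mu
    cov = x.T @ x / len(pts) + np.eye(2) / 12.0  # pixel-area correction
    w, v = np.linalg.eigh(cov)
    a = 2.0 * math.sqrt(max(w[1], 1e-12))
    b = 2.0 * math.sqrt(max(w[0], 1e-12))
    phi = math.degrees(math.atan2(v[1, 1], v[0, 1])) % 180.0
    return float(mu[0]), float(mu[1]), a, b, phi


def _refine_consistent(filled, origin, cx0, cy0, a0, b0, theta0):
    """Refine all five parameters against the raster-consistency residuals.

    Rasterization is a known, deterministic observation model: a pixel
    center inside the blob must satisfy u <= 1 of the quadratic form, one
    outside must satisfy u >= 1.  Hinge residuals over a thin band around
    the boundary are therefore zero at the true parameters; least squares
    from the contour-fit initialization picks a central point of the
    feasible set.  Falls back to the initial values if the solver fails.
    """
    band = ndimage.binary_dilation(filled, iterations=2) & ~ndimage.binary_erosion(
        filled, iterations=2
    )
    rr, cc = np.nonzero(band)
    if len(rr) < 6:
        return cx0, cy0, a0, b0, theta0
    x = cc + origin[1]
    y = rr + origin[0]
    sgn = np.where(filled[rr, cc], 1.0, -1.0)

    def resid(p):
        cx, cy, a, b, t = p
        c, s = math.cos(t), math.sin(t)
        dx, dy = x - cx, y - cy
        xp = dx * c + dy * s
        yp = -dx * s + dy * c
        u = np.sqrt((xp / a) ** 2 + (yp / b) ** 2)
        return np.maximum(0.0, sgn * (u - 1.0))

    try:
        sol = optimize.least_squares(
            resid, [cx0, cy0, a0, b0, theta0], method="trf", max_nfev=120
        )
    except Exception:
        return cx0, cy0, a0, b0, theta0
    cx, cy, a, b, t = sol.x
    a, b = abs(float(a)), abs(float(b))
    if not (np.isfinite([cx, cy, a, b, t]).all() and min(a, b) > 0):
        return cx0, cy0, a0, b0, theta0
    return float(cx), float(cy), a, b, float(t)


def fit_ellipse(pixels: Iterable[tuple[int, int]] | np.ndarray) -> Ellipse:
    """Direct least-squares ellipse fit to a set of (row, col) pixels.

    The conic is fitted, with the ellipse constraint of the direct
    (Fitzgibbon-type) method, to the subpixel outline of the hole-filled
    pixel set: the algebraic fit applied to the filled region itself
    recovers an interior level set and systematically shrinks the axes, so
    the marching-squares contour at level 0.5 is used as the point set.
    The fit is then polished against the rasterization model itself (pixel
    centers inside the blob must fall inside the ellipse, and vice versa);
    a second-moment fit is the fallback when the contour fit is degenerate.

    Returns an unoriented ellipse (``phi`` in [0, 180), ``depth`` 0).

    Raises
    ------
    FitError
        For fewer than 5 distinct pixels or a degenerate (e.g. collinear)
        configuration.
    """
    pts = np.asarray(sorted(set(map(tuple, np.asarray(list(pixels), dtype=int)))))
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise FitError(f"need >= 5 distinct pixels, got {0 if pts.ndim != 2 else len(pts)}")
    rows, cols = pts[:, 0], pts[:, 1]
    # degenerate configurations: all pixels on one line
    if np.linalg.matrix_rank(np.c_[cols - cols.mean(), rows - rows.mean()]) < 2:
        raise FitError("pixel set is collinear; no ellipse fits")

    r0, c0 = rows.min(), cols.min()
    grid = np.zeros((rows.max() - r0 + 3, cols.max() - c0 + 3), dtype=bool)
    grid[rows - r0 + 1, cols - c0 + 1] = True
    filled = ndimage.binary_fill_holes(grid)

    fr, fc = np.nonzero(filled)
    filled_xy = np.c_[fc + (c0 - 1), fr + (r0 - 1)].astype(float)

    params = None
    contours = find_contours(filled.astype(float), 0.5)
    if contours:
        outline = max(contours, key=len)
        xy = np.c_[outline[:, 1] + (c0 - 1), outline[:, 0] + (r0 - 1)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = EllipseModel.from_estimate(xy)
        if model:
            (cx, cy), (a, b), theta = model.center, model.axis_lengths, model.theta
            if np.isfinite([cx, cy, a, b, theta]).all() and min(a, b) > 0:
                # start from the region centroid (better localized than the
                # conic center on thin blobs) and polish everything against
                # the raster-consistency residuals
                mx, my = filled_xy.mean(axis=0)
                cx, cy, a, b, theta = _refine_consistent(
                    filled, (r0 - 1, c0 - 1), float(mx), float(my), a, b, theta
                )
                params = (cx, cy, float(a), float(b), math.degrees(theta) % 180.0)
    if params is None:
        # ragged/tiny blobs: fall back to the (filled-region-exact) moment fit
        params = _moment_fit(filled_xy)

    cx, cy, a, b, phi = params
    if a < b:
        a, b = b, a
        phi = (phi + 90.0) % 180.0
    if not (np.isfinite([cx, cy, a, b]).all() and b > 0):
        raise FitError("degenerate conic: fitted parameters are not an ellipse")
    return Ellipse(cx=cx, cy=cy, a=a, b=b, phi=phi % 180.0, oriented=False, depth=0)


def ellipse_halves(
    e: Ellipse, image_size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Split the rasterization along the minor axis into (front, back) masks.

    "Front" is the half in the direction of ``phi``; pixels exactly on the
    dividing line belong to the front half.  The two masks partition
    ``rasterize_ellipse(e, image_size)`` exactly.
    """
    full = rasterize_ellipse(e, image_size)
    xp, _ = _ellipse_frame(e, image_size)
    front = full & (xp >= 0)
    back = full & ~(xp >= 0)
    return front, back


# ---------------------------------------------------------------------------
# annotation I/O (JSON schema, lossless round trip)

_ELLIPSE_KEYS = ("cx", "cy", "a", "b", "phi", "oriented", "depth")


def _ellipse_to_record(e: Ellipse) -> dict:
    return {
        "cx": e.cx, "cy": e.cy, "a": e.a, "b": e.b, "phi": e.phi,
        "oriented": bool(e.oriented), "depth": int(e.depth),
    }


def _ellipse_from_record(rec: dict, image_id: str, index: int) -> Ellipse:
    for key in _ELLIPSE_KEYS:
        if key not in rec:
            raise AnnotationParseError(
                f"image {image_id!r}: ellipse #{index} is missing field {key!r}"
            )
    try:
        return Ellipse(
            cx=float(rec["cx"]), cy=float(rec["cy"]),
            a=float(rec["a"]), b=float(rec["b"]), phi=float(rec["phi"]),
            oriented=bool(rec["oriented"]), depth=int(rec["depth"]),
        )
    except (TypeError, ValueError, InvalidEllipseError) as exc:
        raise AnnotationParseError(f"image {image_id!r}: ellipse #{index}: {exc}") from exc


def write_annotations(sets: Sequence[AnnotationSet], path) -> None:
    """Write annotation sets as the package's JSON schema."""
    payload = [
        {
            "image_id": s.image_id,
            "height": int(s.image_size[0]),
            "width": int(s.image_size[1]),
            "ellipses": [_ellipse_to_record(e) for e in s.ellipses],
        }
        for s in sets
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_annotations(path) -> list[AnnotationSet]:
    """Read annotation sets written by :func:`write_annotations`."""
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise AnnotationParseError("annotation file must contain a top-level list")
    out = []
    for rec in payload:
        image_id = rec.get("image_id", "<missing image_id>")
        for key in ("image_id", "height", "width", "ellipses"):
            if key not in rec:
                raise AnnotationParseError(f"image {image_id!r}: missing field {key!r}")
        ellipses = [
            _ellipse_from_record(er, image_id, i) for i, er in enumerate(rec["ellipses"])
        ]
        out.append(
            AnnotationSet(
                image_id=str(rec["image_id"]),
                image_size=(int(rec["height"]), int(rec["width"])),
                ellipses=ellipses,
            )
        )
    return out
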