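"""From network outputs to oriented ellipse detections.

Two extraction routes mirror the two segmentation styles:

* **categorical route** — blobs of the *inner core* class are found with a
  connected-component search, an ellipse is fitted to each blob and scaled
  back up by the inverse of the core scale (the core label is a scaled-down
  copy of the annotated ellipse, so touching animals stay separable);
* **embedding route** — pixel embeddings under the predicted foreground
  mask are clustered with HDBSCAN (density-based, hierarchical, noise
  aware), and an ellipse is fitted to each cluster's pixels.

When a body-part output is available, the head-class pixel counts in the
two ellipse halves resolve the 180-degree orientation ambiguity of the
fitted major axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.measure import label as cc_label
from sklearn.cluster import HDBSCAN

from .ellipse import Ellipse, FitError, ellipse_halves, fit_ellipse, scale_ellipse

__all__ = [
    "ClusteringConfig",
    "Detection",
    "threshold_binary",
    "connected_blobs",
    "extract_from_categorical",
    "cluster_embeddings",
    "extract_from_instances",
    "resolve_orientation",
]

logger = logging.getLogger(__name__)

_REFERENCE_AREA = 640 * 512  # resolution at which the default cluster size was validated


@dataclass(frozen=True)
class ClusteringConfig:
    """HDBSCAN parameters for the embedding route.

    ``min_cluster_size`` is the minimum number of pixels one animal may
    cover.  The default 100 holds at the 640x512 working resolution; for
    smaller images it is scaled by the area ratio (never below 5).
    ``min_samples`` (the neighbour count of the density estimate) defaults
    to the *configured* ``min_cluster_size`` without area scaling — the
    smoothing that validated the clustering is a property of the embedding
    distribution, not of the image size, and a too-local density estimate
    chains distinct instances together.
    """

    min_cluster_size: int = 100
    min_samples: int | None = None
    noise_policy: str = "discard"  # or "nearest-cluster"

    def __post_init__(self) -> None:
        if self.min_cluster_size < 5:
            raise ValueError("min_cluster_size must be >= 5")
        if self.min_samples is not None and self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.noise_policy not in ("discard", "nearest-cluster"):
            raise ValueError(f"unknown noise_policy {self.noise_policy!r}")

    def scaled_min_cluster_size(self, image_size: tuple[int, int]) -> int:
        h, w = image_size
        if h * w >= _REFERENCE_AREA:
            return self.min_cluster_size
        return max(5, round(self.min_cluster_size * (h * w) / _REFERENCE_AREA))


@dataclass(frozen=True)
class Detection:
    """One extracted animal: fitted (possibly up-scaled) ellipse + provenance."""

    ellipse: Ellipse
    pixel_count: int
    source: str  # "categorical" or "embedding"

    def __post_init__(self) -> None:
        if self.pixel_count < 5:
            raise ValueError("a detection needs at least 5 supporting pixels")


def threshold_binary(prob_map: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Foreground mask ``p >= tau`` (ties count as foreground)."""
    if not (0.0 < tau < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {tau}")
    return np.asarray(prob_map) >= tau


def connected_blobs(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components as (n, 2) pixel arrays, largest first."""
    lab, n = cc_label(np.asarray(mask, dtype=bool), connectivity=2, return_num=True)
    blobs = [np.argwhere(lab == i) for i in range(1, n + 1)]
    return sorted(blobs, key=len, reverse=True)


def _fit_blob(pixels: np.ndarray, source: str) -> Detection | None:
    try:
        e = fit_ellipse(pixels)
    except FitError as exc:
        logger.info("skipping %s blob of %d pixels: %s", source, len(pixels), exc)
        return None
    return Detection(ellipse=e, pixel_count=len(pixels), source=source)


def extract_from_categorical(
    cat_map: np.ndarray, core_scale: float = 0.5, min_pixels: int = 20
) -> list[Detection]:
    """Detections from a 3-class map: fit to core blobs, scale up by 1/core_scale."""
    if not (0.0 < core_scale < 1.0):
        raise ValueError(f"core_scale must be in (0, 1), got {core_scale}")
    floor = max(min_pixels, 5)
    out = []
    for blob in connected_blobs(np.asarray(cat_map) == 2):
        if len(blob) < floor:
            continue
        det = _fit_blob(blob, "categorical")
        if det is not None:
            out.append(replace(det, ellipse=scale_ellipse(det.ellipse, 1.0 / core_scale)))
    return out


def cluster_embeddings(
    emb: np.ndarray, fg_mask: np.ndarray, cfg: ClusteringConfig | None = None
) -> np.ndarray:
    """Instance map from HDBSCAN clustering of masked pixel embeddings.

    Only pixels under ``fg_mask`` are clustered; background pixels are never
    assigned.  Noise pixels become background (``discard``) or join the
    cluster with the nearest mean (``nearest-cluster``).
    """
    cfg = cfg or ClusteringConfig()
    emb = np.asarray(emb)
    mask = np.asarray(fg_mask, dtype=bool)
    if emb.shape[:2] != mask.shape:
        raise ValueError(f"spatial shapes differ: {emb.shape[:2]} vs {mask.shape}")
    out = np.zeros(mask.shape, dtype=np.int32)
    pts = emb[mask]
    mcs = cfg.scaled_min_cluster_size(mask.shape)
    if len(pts) < mcs:
        return out
    ms = min(cfg.min_samples or cfg.min_cluster_size, max(len(pts) - 1, 1))
    labels = (
        HDBSCAN(min_cluster_size=mcs, min_samples=ms, copy=True)
        .fit(pts.astype(np.float64))
        .labels_
    )
    if labels.max(initial=-1) < 0:
        return out
    if cfg.noise_policy == "nearest-cluster" and (labels < 0).any():
        means = np.stack([pts[labels == k].mean(axis=0) for k in range(labels.max() + 1)])
        noise = labels < 0
        d = np.abs(pts[noise, None, :] - means[None, :, :]).sum(axis=2)
        labels[noise] = d.argmin(axis=1)
    vals = np.where(labels >= 0, labels + 1, 0)
    out[mask] = vals
    return out


def extract_from_instances(instance_map: np.ndarray, min_pixels: int = 20) -> list[Detection]:
    """Fit one ellipse per instance id with enough supporting pixels."""
    floor = max(min_pixels, 5)
    out = []
    instance_map = np.asarray(instance_map)
    for cid in np.unique(instance_map):
        if cid == 0:
            continue
        pixels = np.argwhere(instance_map == cid)
        if len(pixels) < floor:
            logger.info("skipping instance %d with %d pixels", cid, len(pixels))
            continue
        det = _fit_blob(pixels, "embedding")
        if det is not None:
            out.append(det)
    return out


def resolve_orientation(
    dets: list[Detection], bodypart_map: np.ndarray
) -> list[Detection]:
    """Point each detection's ``phi`` at the ellipse half holding more head pixels.

    Ties and ellipses without head pixels stay unoriented (``phi`` keeps the
    fitted axis mod 180).
    """
    bodypart_map = np.asarray(bodypart_map)
    image_size = bodypart_map.shape
    out = []
    head = bodypart_map == 2
    for det in dets:
        front, back = ellipse_halves(det.ellipse, image_size)
        n_front = int(np.count_nonzero(head & front))
        n_back = int(np.count_nonzero(head & back))
        e = det.ellipse
        if n_front > n_back:
            e = replace(e, oriented=True)
        elif n_back > n_front:
            e = replace(e, phi=(e.phi + 180.0) % 360.0, oriented=True)
        else:
            e = replace(e, phi=e.phi % 180.0, oriented=False)
        out.append(replace(det, ellipse=e))
    return out
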