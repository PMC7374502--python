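"""Deterministic generator of overhead pen scenes with exact ellipse labels.

The generator emulates the statistical structure of overhead pig-pen
footage at desk scale: several elliptical animal bodies per image, a
configurable fraction of partially overlapping pairs with known depth
order, a brighter head cap that makes the orientation learnable, per-camera
background textures (so a held-out-camera split is meaningful), optional
grayscale "night vision" frames, occasional low-contrast lens-dirt
blotches, and additive sensor noise.  Realism is deliberately minimal --
shaded ellipses, not animal renderings -- because the segmentation
algorithms, not photorealism, are under test.

Scenes are pure functions of ``(config, index, camera)``: the same inputs
give byte-identical images and annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .ellipse import AnnotationSet, Ellipse, rasterize_ellipse, write_annotations

__all__ = ["SceneConfig", "PlacementError", "generate_scene", "generate_dataset"]


class PlacementError(RuntimeError):
    """An animal could not be placed under the overlap constraints."""


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the scene generator (defaults are the desk-scale study setup)."""

    image_size: tuple[int, int] = (128, 128)  # (height, width)
    n_animals: tuple[int, int] = (3, 8)  # inclusive range per scene
    a_range: tuple[float, float] = (10.0, 18.0)  # semi-major axis, px
    b_range: tuple[float, float] = (4.0, 9.0)  # semi-minor axis, px
    overlap_fraction: float = 0.3  # target fraction of animals touching another
    night_mode_prob: float = 0.25  # grayscale infrared-style frames
    dirt_prob: float = 0.1  # low-contrast lens blotches
    noise_sigma: float = 4.0  # additive Gaussian noise, 8-bit units
    head_fraction: float = 0.4  # major-axis share of the bright head cap
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a_range", "b_range", "n_animals"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range {name}={getattr(self, name)}")
        for name in ("overlap_fraction", "night_mode_prob", "dirt_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.b_range[1] >= self.a_range[0]:
            raise ValueError("b_range must lie strictly below a_range (a > b)")


def _camera_background(cfg: SceneConfig, camera: int) -> np.ndarray:
    """Static floor texture of one camera (smooth blotches over a base tone)."""
    h, w = cfg.image_size
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 7919, camera]))
    base = rng.uniform(55.0, 100.0)
    blotch = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=rng.uniform(5.0, 10.0))
    blotch *= 18.0 / max(blotch.std(), 1e-6)
    grain = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=1.2) * 5.0
    return base + blotch + grain


def _sample_animal(cfg: SceneConfig, rng: np.random.Generator, margin_ok) -> Ellipse:
    h, w = cfg.image_size
    a = rng.uniform(*cfg.a_range)
    b = rng.uniform(*cfg.b_range)
    cx = rng.uniform(a, w - 1 - a)
    cy = rng.uniform(a, h - 1 - a)
    phi = rng.uniform(0.0, 360.0)
    return Ellipse(cx=cx, cy=cy, a=a, b=b, phi=phi, oriented=True, depth=0)


def _place_animals(cfg: SceneConfig, rng: np.random.Generator) -> list[Ellipse]:
    n = int(rng.integers(cfg.n_animals[0], cfg.n_animals[1] + 1))
    if n == 0:
        return []
    last_error: PlacementError | None = None
    for _ in range(20):  # a fresh layout usually resolves a cornered partner
        try:
            return _try_layout(cfg, rng, n)
        except PlacementError as exc:
            last_error = exc
    raise last_error


def _try_layout(cfg: SceneConfig, rng: np.random.Generator, n: int) -> list[Ellipse]:
    h, w = cfg.image_size
    n_pairs = round(cfg.overlap_fraction * n / 2.0)
    n_base = n - n_pairs

    placed: list[Ellipse] = []
    masks: list[np.ndarray] = []
    for i in range(n_base):
        for attempt in range(100):
            e = _sample_animal(cfg, rng, None)
            m = rasterize_ellipse(e, cfg.image_size)
            if all(not (m & pm).any() for pm in masks):
                placed.append(e)
                masks.append(m)
                break
        else:
            raise PlacementError(
                f"could not place disjoint animal {i + 1}/{n_base} in a {h}x{w} "
                f"frame after 100 attempts (axes {cfg.a_range})"
            )
    base_ids = rng.permutation(n_base)[:n_pairs]
    for i, bi in enumerate(base_ids):
        host = placed[bi]
        for attempt in range(100):
            a = rng.uniform(*cfg.a_range)
            b = rng.uniform(*cfg.b_range)
            ang = rng.uniform(0.0, 2 * np.pi)
            dist = rng.uniform(0.5, 0.85) * (host.b + b)
            cx = host.cx + dist * np.cos(ang)
            cy = host.cy + dist * np.sin(ang)
            if not (a <= cx <= w - 1 - a and a <= cy <= h - 1 - a):
                continue
            e = Ellipse(cx=cx, cy=cy, a=a, b=b, phi=rng.uniform(0, 360), oriented=True)
            m = rasterize_ellipse(e, cfg.image_size)
            touches_host = (m & masks[bi]).any()
            touches_other = any(
                (m & pm).any() for j, pm in enumerate(masks) if j != bi
            )
            if touches_host and not touches_other:
                placed.append(e)
                masks.append(m)
                break
        else:
            raise PlacementError(
                f"could not place overlapping partner {i + 1}/{n_pairs} after 100 attempts"
            )
    order = rng.permutation(len(placed))
    return [
        Ellipse(cx=e.cx, cy=e.cy, a=e.a, b=e.b, phi=e.phi, oriented=True, depth=int(d))
        for e, d in zip(placed, order)
    ]


def generate_scene(
    cfg: SceneConfig, index: int, camera: int = 0
) -> tuple[np.ndarray, AnnotationSet]:
    """Render scene ``index`` of ``camera``; returns (uint8 HxWx3 image, annotation)."""
    h, w = cfg.image_size
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, camera, index]))
    animals = _place_animals(cfg, rng)
    ann = AnnotationSet(image_id=f"cam{camera}_scene{index:05d}", image_size=(h, w), ellipses=animals)

    img = _camera_background(cfg, camera).copy()
    yy, xx = np.mgrid[0:h, 0:w]
    for _, e in ann.by_depth(farthest_first=True):
        mask = rasterize_ellipse(e, cfg.image_size)
        r = np.radians(e.phi)
        c, s = np.cos(r), np.sin(r)
        xp = (xx - e.cx) * c + (yy - e.cy) * s
        yp = -(xx - e.cx) * s + (yy - e.cy) * c
        # body tones stay below every head tone so head ends are distinguishable
        body = rng.uniform(155.0, 195.0)
        shade = body * (1.0 - 0.25 * np.abs(yp) / e.b)  # darker toward the flanks
        img[mask] = shade[mask]
        head = mask & (xp >= e.a * (1.0 - 2.0 * cfg.head_fraction))
        img[head] = np.clip(shade[head] + 45.0, 0.0, 255.0)

    if rng.random() < cfg.dirt_prob:
        blob = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=rng.uniform(8, 14))
        blob = np.clip(blob / max(blob.std(), 1e-6), 0.0, None)
        img = img * (1.0 - 0.5 * np.minimum(blob, 1.0)) + img.mean() * 0.5 * np.minimum(blob, 1.0)

    night = rng.random() < cfg.night_mode_prob
    img = img + rng.normal(0.0, cfg.noise_sigma, (h, w))
    img = np.clip(img, 0.0, 255.0)
    if night:
        rgb = np.repeat(img[..., None], 3, axis=-1)
    else:
        # mild color cast so day frames are genuinely 3-channel
        tint = np.array([1.0, 0.96, 0.88])
        rgb = np.clip(img[..., None] * tint, 0.0, 255.0)
    return rgb.astype(np.uint8), ann


def generate_dataset(
    cfg: SceneConfig,
    n_images: int,
    out_dir,
    n_cameras: int = 5,
    test_camera: int | None = None,
) -> dict:
    """Write ``n_images`` scenes + annotations + a manifest to ``out_dir``.

    Images cycle over ``n_cameras`` simulated cameras (distinct background
    textures); scenes of ``test_camera`` (default: the last) are tagged
    ``split="test"`` to mimic a held-out-pen evaluation protocol.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    test_camera = n_cameras - 1 if test_camera is None else test_camera
    annotations, records = [], []
    for index in range(n_images):
        camera = index % n_cameras
        image, ann = generate_scene(cfg, index, camera=camera)
        fname = f"{ann.image_id}.png"
        iio.imwrite(out / fname, image)
        night = bool((image[..., 0] == image[..., 1]).all() and (image[..., 1] == image[..., 2]).all())
        annotations.append(ann)
        records.append(
            {
                "image_id": ann.image_id,
                "file": fname,
                "camera": camera,
                "split": "test" if camera == test_camera else "train",
                "index": index,
                "night": night,
                "n_animals": len(ann.ellipses),
            }
        )
    write_annotations(annotations, out / "annotations.json")
    manifest = {
        "config": asdict(cfg),
        "n_images": n_images,
        "n_cameras": n_cameras,
        "test_camera": test_camera,
        "images": records,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
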