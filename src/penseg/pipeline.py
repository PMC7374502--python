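"""End-to-end orchestration: labels -> training -> inference -> evaluation.

The four experiment variants differ only in the network heads:

========================  =============================
head set                  heads
========================  =============================
``binary``                binary
``categorical``           categorical
``combined``              binary + embedding
``combined-bodypart``     bodypart + embedding
========================  =============================

Inference routes per head set: the categorical variant extracts ellipses
from inner-core blobs and scales them up; the combined variants cluster the
masked pixel embedding with HDBSCAN and fit ellipses to the clusters; the
body-part variant additionally resolves the head-side orientation.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .ellipse import AnnotationSet, Ellipse
from .evaluation import (
    MatchReport,
    MetricValues,
    evaluate_dataset,
    jaccard_accuracy,
    match_segments,
)
from .labels import LabelMaps, render_all, render_instance_map, refit_ground_truth
from .network import HeadSpec, NetworkConfig, TrainConfig, UNet, build_network, train
from .postprocess import (
    Detection,
    cluster_embeddings,
    extract_from_categorical,
    extract_from_instances,
    resolve_orientation,
    threshold_binary,
)

__all__ = [
    "HEAD_SETS",
    "experiment_heads",
    "render_dataset_labels",
    "train_experiment",
    "pad_to_stride",
    "infer_detections",
    "adjusted_ground_truth",
    "evaluate_detections",
]

HEAD_SETS = ("binary", "categorical", "combined", "combined-bodypart")


def experiment_heads(head_set: str, embedding_dim: int = 8) -> tuple[HeadSpec, ...]:
    if head_set == "binary":
        return (HeadSpec("binary"),)
    if head_set == "categorical":
        return (HeadSpec("categorical"),)
    if head_set == "combined":
        return (HeadSpec("binary"), HeadSpec("embedding", out_channels=embedding_dim))
    if head_set == "combined-bodypart":
        return (HeadSpec("bodypart"), HeadSpec("embedding", out_channels=embedding_dim))
    raise ValueError(f"unknown head set {head_set!r}; expected one of {HEAD_SETS}")


def render_dataset_labels(annotations: list[AnnotationSet], cfg: RunConfig) -> list[LabelMaps]:
    return [
        render_all(ann, core_scale=cfg.labels.core_scale, head_fraction=cfg.labels.head_fraction)
        for ann in annotations
    ]


def train_experiment(
    images: list[np.ndarray],
    labels: list[LabelMaps],
    head_set: str,
    cfg: RunConfig,
    input_channels: int = 3,
) -> tuple[UNet, list[dict[str, float]]]:
    """Build and train the network of one experiment variant."""
    net_cfg = NetworkConfig(
        input_channels=input_channels,
        stages=cfg.network.stages,
        base_width=cfg.network.base_width,
        heads=experiment_heads(head_set, cfg.network.embedding_dim),
        coord_features=cfg.network.coord_features,
    )
    model = build_network(net_cfg, seed=cfg.train.seed)
    tcfg = TrainConfig(
        learning_rate=cfg.train.learning_rate,
        epochs=cfg.train.epochs,
        batch_size=cfg.train.batch_size,
        seed=cfg.train.seed,
        augment=cfg.train.augment,
        cosine_decay=cfg.train.cosine_decay,
        disc=cfg.loss,
    )
    scaled = [np.asarray(im, dtype=np.float32) / 255.0 for im in images]
    history = train(model, scaled, labels, tcfg)
    return model, history


def pad_to_stride(image: np.ndarray, stages: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Symmetrically pad (edge mode) so H and W divide 2**stages."""
    d = 2**stages
    h, w = image.shape[:2]
    ph, pw = (-h) % d, (-w) % d
    if ph == 0 and pw == 0:
        return image, (0, 0)
    pad = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="edge"), (ph // 2, pw // 2)


def infer_detections(
    model: UNet, image: np.ndarray, head_set: str, cfg: RunConfig
) -> tuple[list[Detection], dict[str, np.ndarray]]:
    """Run one image through the model and the matching extraction route.

    Returns the detections (in original image coordinates) and the raw head
    outputs (cropped back to the original size).
    """
    img = np.asarray(image, dtype=np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    h, w = img.shape[:2]
    padded, (oy, ox) = pad_to_stride(img, model.cfg.stages)
    outputs = model.predict(padded)
    outputs = {k: v[oy : oy + h, ox : ox + w] for k, v in outputs.items()}

    pp = cfg.postprocess
    if head_set == "categorical":
        cat = outputs["categorical"].argmax(axis=-1)
        dets = extract_from_categorical(cat, core_scale=cfg.labels.core_scale, min_pixels=pp.min_pixels)
        outputs["categorical_map"] = cat
        return dets, outputs
    if head_set == "binary":
        # each separate blob of the thresholded mask is read as one animal
        from skimage.measure import label as cc_label

        mask = threshold_binary(outputs["binary"][..., 0], pp.tau)
        dets = extract_from_instances(cc_label(mask, connectivity=2), min_pixels=pp.min_pixels)
        outputs["binary_mask"] = mask
        return dets, outputs

    # combined routes: foreground mask + embedding clustering
    if head_set == "combined":
        mask = threshold_binary(outputs["binary"][..., 0], pp.tau)
    elif head_set == "combined-bodypart":
        # body and head together form the foreground; within it, the larger
        # of the two animal-class probabilities decides body vs head
        probs = outputs["bodypart"]
        mask = probs[..., 1] + probs[..., 2] > probs[..., 0]
        bp = np.zeros(mask.shape, dtype=np.uint8)
        bp[mask] = 1
        bp[mask & (probs[..., 2] > probs[..., 1])] = 2
        outputs["bodypart_map"] = bp
    else:
        raise ValueError(f"unknown head set {head_set!r}")
    inst = cluster_embeddings(outputs["embedding"], mask, pp.clustering)
    dets = extract_from_instances(inst, min_pixels=pp.min_pixels)
    outputs["instance_map"] = inst
    outputs["fg_mask"] = mask
    if head_set == "combined-bodypart":
        dets = resolve_orientation(dets, outputs["bodypart_map"])
    return dets, outputs


def adjusted_ground_truth(ann: AnnotationSet) -> tuple[np.ndarray, dict[int, Ellipse]]:
    """Exclusive GT instance map + {map id -> adjusted ellipse} for evaluation.

    Ground truth is the *refit* annotation: ellipses fitted to the visible
    pixels of the rendered instance map, so fully painted-over animals drop
    out and partially covered ones are compared by their visible footprint.
    """
    instance = render_instance_map(ann)
    adjusted, dropped = refit_ground_truth(ann)
    for i in dropped:
        instance[instance == i + 1] = 0
    mapping = {i + 1: e for i, e in enumerate(adjusted) if e is not None}
    return instance, mapping


def evaluate_detections(
    per_image: list[tuple[list[Detection], AnnotationSet]],
    pred_maps: list[dict[str, np.ndarray]] | None = None,
    cfg: RunConfig | None = None,
) -> tuple[MetricValues, list[dict]]:
    """Dataset-level metrics for (detections, annotation) pairs.

    When raw head outputs are given, binary / categorical Jaccard indices
    are included (per image, averaged over the set).
    """
    cfg = cfg or RunConfig()
    entries = []
    for i, (dets, ann) in enumerate(per_image):
        gt_map, gt_ellipses = adjusted_ground_truth(ann)
        report: MatchReport = match_segments(dets, gt_map)
        entry = {
            "image_id": ann.image_id,
            "report": report,
            "pred": dets,
            "gt_ellipses": gt_ellipses,
        }
        if pred_maps is not None:
            out = pred_maps[i]
            gt_binary = (render_instance_map(ann) > 0).astype(np.uint8)
            if "binary_mask" in out:
                entry["binary_jaccard"] = jaccard_accuracy(out["binary_mask"], gt_binary, "binary")
            elif "fg_mask" in out:
                entry["binary_jaccard"] = jaccard_accuracy(out["fg_mask"], gt_binary, "binary")
            if "categorical_map" in out:
                from .labels import render_categorical

                gt_cat = render_categorical(ann, cfg.labels.core_scale)
                entry["categorical_jaccard"] = jaccard_accuracy(out["categorical_map"], gt_cat, "categorical")
        entries.append(entry)
    return evaluate_dataset(entries)
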