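"""Training objectives as pure array functions.

Four objectives drive the four experiment variants:

* binary cross-entropy for foreground/background segmentation;
* categorical cross-entropy for the 3-class distance and body-part encodings;
* a discriminative pixel-embedding loss for instance separation, built from a
  variance (pull) term, a distance (push) term and a regularization term,
  each hinged at margins ``delta_v`` / ``delta_d``:

  .. math::

      L_{reg}  &= \\frac1C \\sum_c \\lVert\\mu_c\\rVert_1 \\\\
      L_{var}  &= \\frac1C \\sum_c \\frac1{N_c} \\sum_{i}
                  [\\lVert\\mu_c - x_i\\rVert_1 - \\delta_v]_+^2 \\\\
      L_{dist} &= \\frac1{C(C-1)} \\sum_{c_A \\ne c_B}
                  [2\\delta_d - \\lVert\\mu_{c_A} - \\mu_{c_B}\\rVert_1]_+^2 \\\\
      L &= \\alpha L_{var} + \\beta L_{dist} + \\gamma L_{reg}

  with the L1 norm throughout and :math:`[x]_+ = \\max(0, x)`.  The
  background counts as one of the ``C`` objects (the animals plus the
  background); pixels of the same instance are pulled within ``delta_v`` of
  their mean embedding, and means of different instances are pushed to at
  least ``2 delta_d`` apart.

All functions are framework-free; :func:`discriminative_loss_grad` provides
the analytic gradient used by the trainer (means are *not* treated as
constants — the gradient flows through them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscriminativeConfig",
    "ClusterStats",
    "hinge",
    "binary_cross_entropy",
    "categorical_cross_entropy",
    "discriminative_loss",
    "discriminative_loss_grad",
]

_EPS = 1e-7  # probability clamp before logs


@dataclass(frozen=True)
class DiscriminativeConfig:
    """Margins and term weights of the discriminative loss.

    Defaults: ``delta_v=0.1`` (tightened pull margin, which sharpens the
    clusters handed to the density-based postprocessing), ``delta_d=1.5``,
    ``alpha=beta=1.0``, ``gamma=0.001``.  ``include_background`` controls
    whether background pixels form one of the C clusters (default true).
    """

    delta_v: float = 0.1
    delta_d: float = 1.5
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.001
    include_background: bool = True

    def __post_init__(self) -> None:
        if self.delta_v <= 0 or self.delta_d <= 0:
            raise ValueError("margins delta_v and delta_d must be > 0")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class ClusterStats:
    """Per-instance embedding statistics produced by the loss."""

    ids: np.ndarray  # instance ids, in the order of means/counts
    means: np.ndarray  # (C, D) mean embeddings
    counts: np.ndarray  # (C,) pixel counts

    @property
    def n_clusters(self) -> int:
        return len(self.ids)


def hinge(x):
    """Elementwise ``max(0, x)``."""
    return np.maximum(0.0, x)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy over all pixels (probabilities clamped)."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def categorical_cross_entropy(x: np.ndarray, t: np.ndarray) -> float:
    """Mean categorical cross-entropy over pixels; ``t`` must be one-hot."""
    x = np.asarray(x, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if x.shape != t.shape or x.ndim < 2 or x.shape[-1] < 2:
        raise ValueError(f"need matching (..., C>=2) arrays, got {x.shape} vs {t.shape}")
    if not (np.isin(t, (0.0, 1.0)).all() and np.allclose(t.sum(axis=-1), 1.0)):
        raise ValueError("targets must be one-hot along the last axis")
    n = int(np.prod(x.shape[:-1]))
    return float(-np.sum(t * np.log(np.clip(x, _EPS, 1.0))) / n)


def _cluster_stats(emb2d: np.ndarray, labels: np.ndarray, include_background: bool):
    ids = np.unique(labels)
    if not include_background:
        ids = ids[ids != 0]
    means = np.empty((len(ids), emb2d.shape[1]), dtype=emb2d.dtype)
    counts = np.empty(len(ids), dtype=np.int64)
    masks = []
    for k, cid in enumerate(ids):
        sel = labels == cid
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"instance id {cid} has zero pixels")
        means[k] = emb2d[sel].mean(axis=0)
        counts[k] = n
        masks.append(sel)
    return ids, means, counts, masks


def discriminative_loss(
    emb: np.ndarray, instance_map: np.ndarray, cfg: DiscriminativeConfig | None = None
) -> tuple[float, float, float, float, ClusterStats]:
    """Evaluate the discriminative loss.

    Parameters
    ----------
    emb:
        ``(h, w, D)`` embedding field.
    instance_map:
        ``(h, w)`` integer map; id 0 is the background (included as a
        cluster when ``cfg.include_background``; if absent it is omitted).

    Returns
    -------
    (L, L_var, L_dist, L_reg, stats)
        Weighted total and the three unweighted terms; ``L_dist`` is defined
        as 0 when fewer than two clusters exist.
    """
    cfg = cfg or DiscriminativeConfig()
    emb = np.asarray(emb, dtype=np.float64)
    labels = np.asarray(instance_map)
    if emb.shape[:2] != labels.shape:
        raise ValueError(f"spatial shapes differ: {emb.shape[:2]} vs {labels.shape}")
    flat = emb.reshape(-1, emb.shape[-1])
    ids, means, counts, masks = _cluster_stats(flat, labels.ravel(), cfg.include_background)
    c = len(ids)
    if c == 0:
        stats = ClusterStats(ids=ids, means=means, counts=counts)
        return 0.0, 0.0, 0.0, 0.0, stats

    l_reg = float(np.abs(means).sum(axis=1).mean())
    l_var = 0.0
    for k, sel in enumerate(masks):
        d = np.abs(means[k] - flat[sel]).sum(axis=1)
        l_var += float((hinge(d - cfg.delta_v) ** 2).mean())
    l_var /= c

    if c >= 2:
        pair = np.abs(means[:, None, :] - means[None, :, :]).sum(axis=2)
        h = hinge(2.0 * cfg.delta_d - pair) ** 2
        np.fill_diagonal(h, 0.0)
        l_dist = float(h.sum() / (c * (c - 1)))
    else:
        l_dist = 0.0

    total = cfg.alpha * l_var + cfg.beta * l_dist + cfg.gamma * l_reg
    return total, l_var, l_dist, l_reg, ClusterStats(ids=ids, means=means, counts=counts)


def discriminative_loss_grad(
    emb: np.ndarray, instance_map: np.ndarray, cfg: DiscriminativeConfig | None = None
) -> tuple[float, np.ndarray]:
    """Loss value and analytic gradient w.r.t. the embedding field.

    The L1 norm's subgradient uses ``np.sign`` (0 at ties).  The gradient
    includes the dependence of each cluster mean on its member pixels.
    Computation runs in the input's floating dtype (the trainer passes
    float32; pass float64 for reference-grade precision).
    """
    cfg = cfg or DiscriminativeConfig()
    emb = np.asarray(emb)
    if emb.dtype not in (np.float32, np.float64):
        emb = emb.astype(np.float64)
    labels = np.asarray(instance_map).ravel()
    flat = emb.reshape(-1, emb.shape[-1])
    grad = np.zeros_like(flat)
    ids, means, counts, masks = _cluster_stats(flat, labels, cfg.include_background)
    c = len(ids)
    if c == 0:
        return 0.0, grad.reshape(emb.shape)

    # variance term
    l_var = 0.0
    for k, sel in enumerate(masks):
        diff = means[k] - flat[sel]  # (Nc, D)
        dist = np.abs(diff).sum(axis=1)
        act = hinge(dist - cfg.delta_v)
        l_var += float((act**2).mean())
        s = np.sign(diff)  # d||mu - x||_1 / d(mu - x)
        coeff = 2.0 * act / (c * counts[k])  # (Nc,)
        # direct term: d(mu_c - x_i)/dx_i = -I
        grad[sel] += cfg.alpha * (-(coeff[:, None] * s))
        # through the mean: every member moves mu by 1/Nc
        grad[sel] += cfg.alpha * (coeff[:, None] * s).sum(axis=0) / counts[k]
    l_var /= c

    # distance term
    l_dist = 0.0
    if c >= 2:
        pair_diff = means[:, None, :] - means[None, :, :]
        pair = np.abs(pair_diff).sum(axis=2)
        act = hinge(2.0 * cfg.delta_d - pair)
        np.fill_diagonal(act, 0.0)
        l_dist = float((act**2).sum() / (c * (c - 1)))
        sgn = np.sign(pair_diff)
        # dL/dmu_k: ordered pairs (k,B) and (B,k) contribute identically
        dmu = (-4.0 / (c * (c - 1))) * (act[:, :, None] * sgn).sum(axis=1)
        for k, sel in enumerate(masks):
            grad[sel] += cfg.beta * dmu[k] / counts[k]

    # regularization term
    l_reg = float(np.abs(means).sum(axis=1).mean())
    for k, sel in enumerate(masks):
        grad[sel] += cfg.gamma * np.sign(means[k]) / (c * counts[k])

    total = cfg.alpha * l_var + cfg.beta * l_dist + cfg.gamma * l_reg
    return total, grad.reshape(emb.shape)
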