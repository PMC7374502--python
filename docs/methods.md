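# Methods

`penseg` detects individual animals in top-down pen images as oriented
ellipses. This note documents the models and procedures the package
implements, the choices made where the design was genuinely open, and what
the bundled synthetic data can and cannot show.

## Pose representation

Each animal is a five-parameter ellipse `(cx, cy, a, b, phi)` with a
head-direction flag and an integer depth rank (0 = closest to the camera).
Conventions, used everywhere: 0-based pixel coordinates, x = column,
y = row (down); a pixel belongs to an ellipse iff its center satisfies the
closed interior inequality `(x'/a)^2 + (y'/b)^2 <= 1`; `phi` in degrees from
+x toward +y; axes normalized to `a >= b` (compensated by a 90-degree
rotation); ties on dividing lines (the half-ellipse split, the head-cap
boundary) resolve toward the front/head side. Where animals overlap, labels
are rendered farthest-first so the topmost animal overwrites the ones below;
this overwrite applies identically to the instance, 3-class, and body-part
maps so each pixel carries exactly one label.

Because the rendered (occluded) pixel sets are the actual supervision, the
evaluation ground truth is *refit*: a new ellipse is fitted to each
instance's visible pixels; instances with fewer than 5 visible pixels drop
out of the ground truth.

## Label encodings

* **binary** — foreground/background.
* **categorical** — background / outer edge / inner core, where the core is
  the annotated ellipse with both semi-axes scaled by `core_scale`
  (default 0.5, i.e. area x 0.25). Scaling axes rather than area makes the
  extraction up-scaling an exact inverse (x 1/core_scale). Cores of
  touching animals stay disjoint, which is the separation mechanism of the
  categorical route.
* **bodypart** — background / body / head. The head is the elliptical cap
  beyond `x' = a(1 - 2*head_fraction)` toward `phi`; `head_fraction`
  defaults to 0.4 of the major-axis extent and is a config knob, since no
  canonical head geometry exists for ellipse annotations;
  `head_fraction = 0.5` reproduces the exact front half.

## Training objectives

Binary and categorical heads use mean cross-entropy with probabilities
clamped to `[1e-7, 1 - 1e-7]`. The embedding head uses the discriminative
loss (L1 norm, hinges squared after clipping):

    L_reg  = (1/C) sum_c ||mu_c||_1
    L_var  = (1/C) sum_c (1/N_c) sum_i [ ||mu_c - x_i||_1 - delta_v ]_+^2
    L_dist = (1/(C(C-1))) sum_{cA != cB} [ 2 delta_d - ||mu_cA - mu_cB||_1 ]_+^2
    L      = alpha L_var + beta L_dist + gamma L_reg

Defaults: `delta_v = 0.1`, `delta_d = 1.5`, `alpha = beta = 1`,
`gamma = 0.001`, embedding dimension `D = 8`. The background counts as one
of the `C` clusters (configurable via `include_background`; disabling it
destabilized training in our experiments because most pixels then receive
no embedding supervision). `L_dist` is defined as 0 for `C < 2`, the only
consistent limit of the `C(C-1)` normalizer. The analytic gradient
backpropagates through the cluster means (not treating them as constants);
`np.sign` supplies the L1 subgradient, with 0 at exact ties.

## Network

A plain U-Net-scale encoder-decoder written directly on numpy arrays with
explicit backpropagation: per stage two 3x3 convolutions with leaky-ReLU
(slope 0.1), 2x2 average pooling down, nearest-neighbour upsampling and
skip concatenation up, and 1x1 convolution heads (sigmoid / softmax /
linear to match the target). Design notes:

* **Leaky ReLU** rather than ReLU: in a from-scratch network this small,
  dead units are not spare capacity but a real bottleneck; with plain ReLU
  roughly three quarters of the final-stage channels were dead on
  foreground pixels and the (rare) head class was never learned.
* **Input skip into the heads.** The centered input (plus coordinate
  channels) is concatenated onto the final decoder features before the 1x1
  heads. Rationale: the discriminative loss rewards *within-animal
  constancy* of the features it reads, while the body-part head needs
  *within-animal contrast*; with a trunk only as wide as the embedding
  (8 channels vs D = 8), the embedding objective otherwise consumes the
  whole representation. The input skip hands the heads direct appearance
  access at zero parameter cost upstream.
* **Coordinate channels** (normalized x, y appended to the input) give the
  embedding head a positional cue for instance separation — the role the
  very large receptive field of an ImageNet backbone plays at full scale.
* Inputs are shifted by -0.5 (images arrive in [0, 1]).
* He-normal init; Adam; optional cosine annealing of the learning rate to
  a tenth over the run (on by default; the late low-lr phase is what
  tightens the embedding clusters below `delta_v`).
* Heads feed the shared trunk with equal weight by default; per-head
  weights are configurable.
* Augmentation (flips, 90-degree rotations where square, grayscale to mimic
  night vision) multiplies the pair geometries the embedding head sees and
  measurably reduces cluster merges of overlapping animals on the held-out
  camera; it is on in the desk-scale preset.

The default configuration (`stages = 4`, `base_width = 16`) mirrors the
encoder-decoder scale a practitioner would start from; the desk-scale
preset (`RunConfig.desk_scale()`) uses `stages = 4`, `base_width = 8`,
learning rate 3e-3, batch 2, 50 epochs — the fourth stage costs ~10% more
compute and buys the receptive field that separates overlapping animals,
and the small batch doubles the optimizer steps per epoch, which at this
model size improves held-out detection quality while *reducing* wall time.
The package-wide default learning rate of 1e-5 is the published
fine-tuning value for large pretrained backbones; training a
~50k-parameter network from scratch needs the larger step size.

## Postprocessing

* **Categorical route**: 8-connected blobs of the inner-core class (>= 20
  pixels by default; the floor of 5 is the fit's hard minimum), direct
  ellipse fit, axes scaled by `1/core_scale`.
* **Embedding route**: HDBSCAN (scikit-learn implementation) over the
  embeddings of foreground pixels only. `min_cluster_size` defaults to 100
  at the 640x512 working resolution and scales with image area for smaller
  inputs, floored at 5. Noise pixels become background by default
  (`noise_policy = "discard"`) or can join the nearest cluster mean.
* **Foreground mask**: binary-head threshold (p >= tau, tau = 0.5, ties
  foreground) in the combined variant; in the body-part variant the mask is
  where body + head probability exceeds background, and head-vs-body is
  decided between the two animal classes only. This hierarchical reading
  matches the role of the body-part output as "binary segmentation plus
  head side" and makes orientation usable even while the head class is the
  weaker of the two.
* **Orientation**: the fitted ellipse is split along its minor axis; `phi`
  points at the half containing strictly more head-class pixels; ties and
  zero head pixels leave the detection unoriented (`phi` mod 180).

## Ellipse fitting

`fit_ellipse` starts from the direct least-squares (Fitzgibbon-type,
Halir-Flusser-stabilized) conic fit applied to the subpixel
marching-squares contour of the hole-filled pixel set — fitting the filled
region itself is not an option: the algebraic fit then recovers an interior
level set and shrinks the axes by almost 30%. The initial estimate (center
from the region centroid, shape from the conic) is then polished against
the rasterization model: a pixel center inside the blob must satisfy
`u <= 1` of the quadratic form and one outside `u >= 1`, so hinge residuals
over a thin boundary band vanish at the true parameters and least squares
picks a central point of the feasible set. A second-moment fit is the
fallback for degenerate contours. On 1000 random rasterized ellipses
(a in [6, 30], b in [3, a], 96x96 frame) this recovers centers within
0.28 px and axes within 4.3% — the largest relative errors belong to the
smallest (b = 3 px) draws, where they are below 0.25 px absolute, the
raster quantization floor.

Orientation recovery from a binary raster is identifiability-limited: the
orientation signal in the second moments is the eigenvalue gap
(a^2 - b^2)/4, and for near-circular ellipses rasterization noise exceeds
it (a perfect circle constrains no angle at all). Where
`a^2 - b^2 >= 100 px^2` the fitted angle is reliable to well under
2 degrees (empirical max 1.3 over 1000 draws); below that threshold angle
errors up to tens of degrees are expected and the tests do not assert on
them.

## Evaluation

Predicted ellipses are rasterized individually (they may overlap) and
matched one-to-one to the exclusive ground-truth instance map; a pair is a
candidate only at IoU strictly greater than 0.5, and candidates resolve
greedily by descending IoU — for exclusive maps at most one prediction can
exceed 0.5 per ground-truth segment, so greedy matching is optimal (the
test suite verifies this against exhaustive search). PQ is the summed
matched IoU over `|TP| + 0.5 |FP| + 0.5 |FN|`, defined 0 for an empty
denominator. Precision/recall/F1 share the TP/FP/FN sets; TP/FP/FN pool
over images for dataset-level PQ and F1, while Jaccard indices average per
image. Orientation accuracy is the fraction of true positives whose
predicted head direction is within 90 degrees (circular) of the annotated
one; unoriented predictions count as wrong, and true positives whose ground
truth is unoriented are excluded. The 90-degree boundary is the natural
decision threshold for a 180-degree ambiguity.

## Synthetic scenes

The generator emulates overhead pen footage at desk scale: 128x128 frames,
3-8 animals per scene (semi-axes a in [10, 18], b in [4, 9] px), ~30% of
animals partially overlapping a neighbour with known depth order, per-camera
smooth background textures (base tone 55-100), body tones 155-195 with
flank shading, a head cap 45 units brighter (body and head tone ranges are
disjoint so head ends are locally distinguishable, which is the generator's
contract), 25% grayscale night-vision frames, 10% low-contrast lens-dirt
blotches, and additive Gaussian noise (sigma 4). Overlap placement puts
`round(0.3 n / 2)` partner animals in contact with distinct hosts, so the
expected touching fraction matches the knob. Scenes are pure functions of
(config, camera, index).

What passing on this data does **not** show: robustness to deformable,
non-elliptical bodies, real lighting, lens geometry, animal growth, or the
annotation noise of human labellers. The generator tests the framework's
algorithms, not photorealism.

## Desk-scale study and problem sizes

The packaged experiment trains the combined body-part + embedding network
on 200 scenes from four simulated cameras and evaluates on 50 scenes from a
fifth, unseen camera; the single-image experiment overfits one scene for at
most 500 steps and checks that clustering the resulting embedding yields
exactly the annotated instance count; clustering stability re-clusters the
held-out embeddings with `min_cluster_size` in {50, 100, 200} at reference
scale. These sizes were chosen so a full run trains in minutes on one CPU
core while still exercising every pipeline stage; `scripts/acceptance.py`
reruns all of them from scratch.

## Known limitations

* The numpy network trains at desk scale only; there is no GPU path.
* The categorical route cannot separate animals whose *cores* overlap.
* Greedy matching is only guaranteed optimal for exclusive prediction maps;
  for heavily overlapping predicted ellipses it is a documented convention.
* Orientation of near-circular detections is unreliable (see the
  identifiability bound above); such animals rarely occur in the synthetic
  data (b < a by construction).
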