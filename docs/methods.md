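# Methods

`nasalbase` implements an automatic assessment of nasal-base symmetry
from basal-view (submental) photographs. The framework has four stages:
localization of the nasal base, regression of 18 anatomical landmarks,
computation of nine left/right geometry-ratio features, and a fused
CNN + MLP regression of a continuous symmetry score supervised by a
structural-similarity (SSIM) ground truth, with an occlusion-based
explanation overlay. Because clinical photograph collections of this
kind are not redistributable, a seeded parametric renderer supplies
images with exact landmark annotations for training and for every
quantitative check in this repository.

## Landmark schema and geometry features

The nasal base is annotated with 18 named landmarks: pronasale and
subnasale on the columellar midline, and eight left/right pairs (alare,
subalare, midalar point, ala outer-edge point, nostril apex, nostril
base, nostril medial-width point, midcolumellar apex point). "Left"
and "right" refer to image side throughout. The columellar axis is the
line through pronasale and subnasale; inside a basal crop the vertical
reference line (VRL, the facial-midline surrogate) is taken as the line
through subnasale parallel to that axis, because the nasion and
gnathion that define the clinical VRL are outside the field of view.
After standardization the two lines coincide; they are kept as separate
objects because they are conceptually different references.

Each geometry feature is the ratio of a left measurement to its right
counterpart, so perfect mirror symmetry gives 1.0 everywhere:

| i | measurement | definition |
|---|-------------|------------|
| 1 | nostril axis angle | angle (degrees) between the nostril-base→apex segment and the columellar axis |
| 2 | midalar width | perpendicular distance of the midalar point to the columellar axis |
| 3 | subalare–midline distance | perpendicular distance of the subalare to the VRL |
| 4 | alare–axis distance | perpendicular distance of the alare to the columellar axis |
| 5 | midcolumellar apex width | distance of the midcolumellar apex point to the columellar axis |
| 6 | midcolumellar base width | distance of the nostril medial-width point to the columellar axis |
| 7 | nostril width | twice the distance of the nostril medial-width point to the nostril long axis |
| 8 | nostril height | distance between nostril apex and base |
| 9 | ala thickness | distance between midalar and ala outer-edge points |

These definitions are recorded in `geometry.MEASUREMENT_TABLE` so that
independent re-measurement is unambiguous. The feature vector is
mirror-antisymmetric (reflecting the landmarks about the columellar
axis and swapping side labels maps every ratio to its reciprocal),
scale-invariant, and rotation-invariant when the axes are recomputed
from the transformed landmarks. Min–max normalization to the training
extrema maps a feature with a degenerate (constant) training range to
0, since such a feature carries no information.

## Synthetic nasal-base renderer

`synth.NoseParams` describes one nasal base with explicit per-side
measurements (nostril ellipse width/height/axis angle, columella apex
and base half-widths, midalar offset, ala thickness, alare and subalare
offsets) on a 256×256 canvas (default overall scale 70 px). Shapes are
anti-aliased by 4× supersampled rasterization; a low-amplitude,
Gaussian-smoothed, seeded noise field supplies skin texture. A
9-component asymmetry vector perturbs each measurement pair
multiplicatively — left ×exp(v/2), right ×exp(−v/2) — so the i-th
geometry ratio equals exp(v_i) exactly by construction. Components are
drawn from a zero-mean normal whose spread defaults to 0.3 and are
capped at ±0.8 to keep the anatomy plausible.

Every parameter that carries a landmark leaves a visible trace in the
image: the lateral alar bulge terminates exactly at the alare, an alar
rim ellipse spans midalar→ala-outer, and an alar-facial groove marks
the subalare. This mirrors real anatomy, where landmarks sit on
observable structure, and it is what makes the landmark-regression task
well-posed: without it, several landmark positions would be
statistically independent of the pixels and no regressor could place
them.

`embed_in_face` pastes a render at a seeded random position and scale
(0.8–1.25) onto a 512×512 textured background with feathered edges, so
detection requires recognizing nasal structure rather than a paste
seam.

What the renderer does *not* emulate: photographic lighting variation,
skin-tone diversity, pose (pitch/yaw) outside the basal view, hair and
occlusions, and anatomical deformity such as cleft anatomy. Passing
the checks in this repository therefore demonstrates that the pipeline
is implemented correctly and learnable at desk scale, not that its
numeric performance transfers to clinical photographs.

## Detection

A single-stage anchor-grid detector replaces a two-stage region-
proposal detector at desk scale, trained with the same unified loss: a
mean binary log loss −log[p\*p + (1−p\*)(1−p)] over sampled anchors plus
λ times the mean (over anchor locations) of the summed smooth-L1 errors
of the four box offsets on positive anchors; λ defaults to 1. Anchors
are square (32 px at the 128×128 model input) on the conv lattice;
positives are anchors with IoU above the threshold plus the max-IoU
anchor (so every box owns one), negatives below 0.3, others ignored.
The default positive threshold is the conventional 0.7; the scaled-down
training experiments label positives at IoU ≥ 0.5 because a single
anchor shape at this grid otherwise yields too few positive anchors to
train the offsets at every relevant location. Offsets use the standard
center-offset/log-size parameterization. The trunk is four 3×3 conv
blocks (16, 32, 64 channels, stride 2, LeakyReLU 0.1, plus a stride-1
64-channel refinement block) with 1×1 objectness and box heads; one box
(argmax objectness) is kept at inference since each image contains one
nasal base. Training uses Adam (lr 1e-3, step decay) with
best-validation-loss checkpointing; a tiny learning rate of the kind
used to fine-tune large pretrained backbones would starve a small
network trained from scratch, hence the larger default.

Detection quality is reported as precision/recall/F1 at IoU 0.5 with
greedy best-IoU matching, and 11-point interpolated average precision
(mean over recall levels 0.0–1.0 of the maximum precision at or above
each level); with a single class, mAP equals AP.

## Landmark regression

The regressor is a small CNN (four 3×3 stride-2 conv blocks 16/32/64/64,
LeakyReLU 0.1, dense 256, linear 36) mapping a 64×64 grayscale crop to
the 18 landmark coordinates normalized to the crop, trained with the
MAE loss, Adam (lr 1e-3, batch 32, step decay), best-validation
checkpointing. The output bias is initialized to the mean training
constellation so the network learns residuals from the population
average. Training crops come from the ground-truth box (tight landmark
box padded 15 % per side); at inference the detector's predicted box
feeds the crop, and the zoom transforms move coordinates between the
whole-image frame and the normalized crop frame (exact affine inverses
of one another).

Metrics: NME is the per-image *sum* of Euclidean landmark errors
divided by √(box width × height), averaged over images; MAPE is the
mean per-image summed pixel error; MAE and RMSE are over flattened
coordinate residuals; PC is the Pearson correlation of flattened
predicted versus true coordinates (a single scalar).

Ablation utilities reproduce the robustness protocols: perturbing 3–7
landmarks by 1–5 px in one of four axis directions (seeded), and
additive clipped Gaussian pixel noise.

Two training regimes serve different purposes. The crop-based
evaluation protocol trains and tests on exactly-registered
ground-truth-box crops, isolating the regression problem. The deployed
pipeline instead trains the regressor on randomly *jittered* boxes
(center ±7 %, scale ±15 % of the box), because at inference the crop
comes from the detector, whose localization noise would otherwise put
every input slightly out of distribution — without jitter augmentation
the end-to-end feature ratios on symmetric input deviate severely.

## Symmetry scoring

Preprocessing: rotate about the subnasale so the columellar axis is
vertical; crop to the landmark box grown to a *square* (so the resize
to the canonical 128×128 is isotropic and geometry ratios are exactly
preserved); white-mask everything outside the convex hull of the 18
landmarks dilated by 6 px (rasterized by half-plane tests at pixel
centers, which keeps a mirror-symmetric hull's mask mirror-symmetric);
split at the columellar axis. A pixel column containing the axis in
its interior belongs to neither half; when the axis runs along a pixel
boundary the split is clean. The SSIM ground truth compares the left
half with the mirrored right half in grayscale (Gaussian window
σ = 1.5, K1 = 0.01, K2 = 0.03, dynamic range 255), after trimming the
border that is white in both halves so the score reflects the nasal
base rather than the shared blank margin; the result is clamped to
[0, 1]. The right half is the mirrored one by convention.

The tiled representation is the 2×2 grid induced by the columellar axis
and the horizontal midline (left/right × upper/lower, order LU RU LL
RL), each tile resized to 32×32. Tiles are z-scored per color channel
with training-set statistics; geometry features are min–max normalized
with training extrema. The combined model runs a small CNN over the
12-channel tile stack and an MLP (9→32→32) over the normalized
features, concatenates the last hidden layers (48 + 32), and emits one
scalar through a dense head; MAE loss, Adam lr 1e-3, batch 8,
best-validation checkpointing; evaluation reports MAE, RMSE and PC.

Continuous scores map to five ordinal categories (completely symmetric,
very symmetric, slightly symmetric, asymmetric, completely asymmetric)
by thresholds 0.95/0.85/0.70/0.50 on the score — expert-calibratable
and deliberately configurable, since the clinical thresholds are a
matter of rater opinion. Exact matching between two rank lists is the
fraction of identical categories; fine matching accepts being one
ordinal category apart (this reading is consistent with 19 exact plus 4
adjacent agreements out of 30 giving 0.6333 and 0.7666).

## Explanation heatmap

Occlusion importance replaces each tile with the white masking baseline
and measures the absolute change in the predicted score (normalized to
sum 1); occlusion was chosen over gradient saliency because it is
architecture-agnostic and exactly reproducible. Features with
|f_i − 1| above a threshold (default 0.1) are flagged; each flagged
feature contributes the convex hull of its defining landmarks on *both*
sides (asymmetry is a property of the pair), dilated by 5 px; the
combined mask is the union of flagged regions intersected with the area
of tiles whose importance reaches the median. Enlarging the flag
threshold can only shrink the mask. The overlay is rendered as a
translucent red wash on the standardized crop.

## Problem sizes and numerical choices

Scaled-down study sizes used by the test suite and the acceptance
script (chosen to be comfortably learnable on one CPU core):

- detector: 130–140 face-context images, 40–45 epochs, 30 held out;
- landmark regressor: 2 400 crops, 30–35 epochs, 60 held out;
- whole-image vs crop comparison: 190–200 images, 25–30 epochs, shared
  seed and budget for both models;
- combined model: 480 training samples, 250–300 epochs, 120 held out;
- SSIM property checks: 200 seeded renders.

All models run in float32 on a hand-rolled NumPy layer stack (im2col
convolutions, LeakyReLU, dense layers, Adam, the five named
learning-rate schedule families); every run is a pure function of its
seed. Degenerate inputs are handled by convention rather than silently:
coincident pronasale/subnasale, zero-valued measurements, degenerate
boxes, constant pixel channels and unfitted scalers all raise.

## Known limitations

- The 18-landmark definitions are a reconstruction sufficient to
  compute the nine ratios; clinical atlases may differ in detail.
- The renderer's simplicity means learned error rates here are
  optimistic relative to clinical photographs.
- The rank thresholds are not clinically calibrated.
- The heatmap highlights measurement pairs, not a single "guilty" side;
  lateralization beyond the pair requires a population prior that a
  ratio alone does not provide.
- Through the full detect→landmark→score chain, landmark noise on the
  smallest measurements (the columellar widths span only a few pixels
  at crop scale) keeps some predicted ratios more than 0.1 from 1 even
  for symmetric input, so end-to-end heatmaps are rarely empty and the
  predicted score separates symmetric from asymmetric scenes in
  ordering rather than in absolute level. Scores computed from
  ground-truth annotations do not have this limitation.
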