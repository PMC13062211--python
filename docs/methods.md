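# Methods

## Problem and model

`leafseg` implements per-pixel segmentation of leaf damage (disease lesions,
insect feeding marks, miner tunnels) with a *representation-first* design:
a frozen patch-feature encoder provides semantically rich features, and only
a lightweight adapter and decoder are trained on the downstream task.

The DinoUnet architecture composes five stages on an RGB image `x`:

1. **Encoder** `f_enc(x) ∈ R^{H/16 × W/16 × C}` — a patch-16 token encoder.
   The package ships a small seeded vision transformer (4 blocks, 4 heads,
   C = 64) so every contract is exercisable on a desk CPU; the
   `external_pretrained` encoder option accepts any callable with the same
   grid contract, which is how an actual large self-supervised foundation
   encoder plugs in. With `encoder_frozen` (default) the encoder receives
   no gradients; repeated evaluations are bit-identical, verified by a
   SHA-256 probe-image checksum before and after training.
2. **Spatial Prior Module** — MaxPool(2) followed by four 3×3 conv blocks
   (widths 16, 32, 32, C_spm = 32; strides 1, 2, 2, 2), giving a final
   stride-16 map aligned with the encoder grid plus intermediate maps at
   strides 2, 4 and 8. The ordering of strides was chosen so that every
   intermediate map is learnable and one exists at each skip resolution the
   decoder consumes; total stride must equal the encoder patch size for the
   final maps to align.
3. **Fusion** — channel concatenation `[f_enc, f_spm]`. Concatenation is
   lossless: both inputs are recoverable by slicing, which the tests assert
   exactly.
4. **Projection** — 1×1 convolution + per-location channel normalisation +
   ReLU to the decoder width C_target = 64.
5. **Decoder** — four ×2 nearest-neighbour upsampling stages with 3×3 conv
   blocks (widths 64, 48, 32, 24); the first three concatenate the
   spatial-prior skip at the matching stride; a 1×1 head and per-pixel
   softmax produce the K-class probability map at input resolution. A
   single stride-16 bottleneck cannot populate four decoder levels, so the
   spatial-prior intermediates serve as the skip connections and the
   projected features as the bottleneck.

A plain symmetric 4-level Unet (widths 16, 32, 48, 64, bottleneck 96) with
the same probability-map contract is the comparison baseline.

Channel widths C = 64, C_spm = 32, C_target = 64 are free parameters chosen
for desk-scale trainability; a production encoder would set C to its own
embedding width.

### Numerical substrate

No deep-learning framework is used: the package contains a compact
reverse-mode automatic-differentiation engine over numpy arrays
(`leafseg.autograd`) with exactly the operations the models need —
broadcasted arithmetic, matmul, softmax/log-softmax, im2col convolution
(input gradients computed as a stride-dilated convolution with the flipped
kernel), 2×2 max pooling, ×2 nearest upsampling, concatenation — plus a
layer library and Adam (`leafseg.nn`). Every operation's gradient is
verified against central finite differences in the test suite. Parameters
are float32; all initialisation flows from explicit seeds, and forward
passes with fixed weights are bitwise reproducible.

## Training objective

Per-pixel cross-entropy plus focal loss, averaged over all pixels of a
batch and summed with equal weight:

    L_CE    = −Σ_c y_c log p̂_c
    L_focal = −Σ_c α_c (1 − p̂_c)^γ y_c log p̂_c
    L_total = L_CE + L_focal

Defaults are the canonical focal setting α_c = 1, γ = 2 (overridable per
class in the run config). The mean-over-pixels reduction makes the loss
scale-invariant across image sizes. Probabilities are clamped at 1e-12
before the log. The training path evaluates the same quantities on raw
logits via log-softmax for numerical stability; tests assert the two paths
agree.

Optimisation: Adam, lr 1e-3, batch 8 — robust small-model defaults,
overridable. Checkpoint selection is by best validation IoU. A non-finite
loss aborts the run with a diagnostic.

## Data

### Synthetic scenes

The generator (`leafseg.synthetic`) emulates two acquisition regimes of
plant-pathology imagery: `simple` (one leaf, near-white lab background) and
`field` (three overlapping leaves, soil/vegetation clutter, stronger
illumination variation). A leaf is an ellipse with low-frequency radial
boundary noise; lesion morphologies are `round_spot` (flea-beetle feeding
marks), `serpentine` (miner tunnels: a dilated random-walk polyline, width
2–5 px, constrained inside the leaf) and `irregular_patch` (rust/mosaic
patches: a high-noise radial polygon). Per-leaf lesion count and total
lesion area fraction are sampled from configurable ranges (defaults 1–3
lesions, 5–15 % of leaf area; the source imagery documents no quantitative
size distribution, so these are free parameters chosen to look plausible).
Illumination jitter is a smooth multiplicative field applied *after* mask
rasterisation, so masks stay exact. Images are quantised to 8 bits at
generation time, making the PNG round-trip bit-exact.

Ground truth is exact by construction: each lesion's pixel area, centroid,
equivalent diameter and perimeter are recorded at painting time, lesions of
the same class are kept ≥ 1 px apart so 8-connected components match the
records one-to-one, and heavily occluded leaf remnants (visible area below
a quarter of the largest leaf) receive no lesions. A lesion that cannot be
placed on the dominant leaf after 60 attempts raises a `GenerationError`
rather than silently truncating.

Per-sample determinism comes from `SeedSequence([scene_seed, index])`,
which is stable across platforms.

What the generator does **not** emulate: photorealistic texture, venation,
species-specific lesion appearance, camera optics, annotation noise.
Passing tests therefore demonstrate that the algorithms are implemented
correctly and that the training loop can recover known structure — not
that the tiny encoder would segment real field imagery.

### Pipeline

Images are resized bilinearly and masks by nearest neighbour (labels
preserved) to a square size divisible by 16, then standardised with
per-channel mean/std computed from the training split. The 7:1:2
train/val/test split uses an explicit rounding rule — test = round(0.2 n),
val = round(0.1 n), train = remainder — with a seeded shuffle at the image
level (no sample ever appears in two subsets).

## Evaluation

Dice, IoU, pixel accuracy, precision, recall and F1 are computed from
per-class confusion counts, with both aggregations reported: *micro* pools
TP/FP/FN over the whole test set, *macro* averages per-class values
unweighted. Conventions: empty-vs-empty overlap scores 1.0; a
zero-denominator precision/recall reports 0.0 with a logged warning. Note
that for a single binary mask pair Dice and IoU obey Dice = 2·IoU/(1+IoU)
exactly (property-tested); published tables that violate this identity are
using some other aggregation, which this package does not attempt to
emulate.

**Lesion geometry.** Per class, 8-connected components of prediction and
reference are matched by maximal pixel overlap (greedy, largest overlap
first, ties toward the larger reference lesion). For each reference lesion
the per-lesion measurement is either the equivalent diameter
√(4·area/π) or the marching-squares perimeter; an unmatched reference
lesion contributes its full measurement as error (a missed lesion), and
false-positive components are not penalised in this statistic. The summary
is the RMSE over all reference lesions; an image set with no reference
lesions of the class yields an explicit empty result (`rmse=None`), not 0.
The perimeter estimator lightly smooths the binary mask (Gaussian σ=0.8 px)
before contouring at the 0.5 level, removing the ~4.7 % staircase
overestimate of marching squares on hard masks; for disks of radius ≥10 px
the estimate is within ~1 % of 2πr (small components below ~5 px radius are
underestimated — a known limitation).

## Interpretability

Per test sample, the frozen encoder grid is global-average-pooled to a
C-vector. The analysis then: (1) projects all vectors to 2-D with seeded
UMAP for visualisation; (2) clusters with k-means (k = number of semantic
classes by default, 10 restarts, seeded) and measures each sample's
Euclidean distance D_i to its own cluster center; (3) Pearson-correlates
D_i with the per-sample lesion IoU (micro over lesion classes within the
sample), reporting r and the two-sided t-test p-value (n−2 df).

**Distance space.** Cluster centers and distances are computed in the
*original pooled-feature space* by default (`distance_space="feature"`),
not in the 2-D UMAP space. This is a deliberate design choice: a 2-D
neighbourhood-preserving embedding does not preserve the radial ordering of
distances in a 64-dimensional feature space, and we measured distance-to-
center in UMAP space to be uncorrelated with injected corruption even when
the feature-space correlation is strong. The UMAP coordinates are retained
for the scatter visualisation, and `distance_space="umap"` reproduces the
alternative reading.

**Coupling experiment.** `noise_coupling_experiment` validates the analysis
end to end on a constructed setting where embedding quality and IoU are
degraded by the same cause: each synthetic sample receives additive
Gaussian image noise of per-sample level σ_i ~ U(0, 0.8), and a copy of its
reference mask is corrupted by reassigning random pixels with probability
0.6·σ_i (standing in for a prediction that degrades with image quality).
Distances are computed from the frozen encoder on the noisy images, IoU
between corrupted and clean masks. The pipeline reports a strongly negative
correlation (r ≈ −0.5 at the default scale), i.e. samples far from their
cluster center segment worse.

## Problem sizes and reproducibility

All quantities in `scripts/acceptance.py` and the test suite are computed
at desk scale, chosen as the package's own study conditions: 64×64 scenes
for training experiments (every architectural contract is
resolution-independent and additionally verified at 128 and 256), an
8-image overfit run (200 steps), a 200-image / 30-epoch train-test
comparison for the recovery benchmark (120 images / 15 epochs in the
acceptance script), and an 80-sample coupling experiment. Two runs with
identical seeds produce identical datasets, training histories and
checkpoints; determinism is asserted in the suite.

## Known limitations

- The shipped encoder is a small randomly initialised ViT: it demonstrates
  the frozen-backbone adaptation machinery but carries no pretrained
  semantics; conclusions about real foundation-model accuracy require
  plugging external weights into the `external_pretrained` hook.
- Nearest-neighbour ×2 upsampling and single-conv decoder blocks favour
  CPU speed over maximal accuracy.
- The synthetic lesion classes are visually separable by colour; absolute
  metric values on these scenes are optimistic relative to real imagery.
- The per-lesion geometry matching is greedy, not optimal assignment;
  pathological many-to-many overlaps may match differently than a Hungarian
  solution would.
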