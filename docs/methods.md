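# Methods

`meningiodet` implements a detection stack for meningioma on 2-D brain MRI
slices: a finite ridgelet decomposition, five pixel-intensity features of the
coefficient grid, a hybrid CNN classifier whose output layer is a spatial
fuzzy c-means (SFCM) clustering, and a probability-based morphological tumor
segmenter. A synthetic phantom generator provides seeded data with exact
ground truth so every stage can be validated end to end without clinical
data. This note records the model, the design decisions taken where the
method leaves choices open, and what the synthetic validation does and does
not establish.

## Finite ridgelet transform

The finite Radon transform (FRAT) of a p x p image, p prime, sums pixels over
the p + 1 families of mod-p lines

    L(k, l) = {(i, j) : j = k i + l (mod p)},  k = 0 .. p-1,
    L(p, l) = {(i, j) : i = l},

giving a (p+1) x p projection grid. Each family partitions the grid, so every
direction's offset sums must add up to the total pixel sum exactly — an
integer identity the test suite asserts without tolerance. Images are
zero-padded to the next prime side (241 for 240, 521 for 512); zero padding
keeps the partition identity exact and matches the black air background of
MRI.

The ridgelet coefficients are produced by a 1-D orthonormal discrete wavelet
transform (Haar by default, depth floor(log2 p), configurable) along the
offset axis of each direction. Because p is odd, a periodized DWT applied
directly is not orthonormal; each projection is therefore zero-padded to the
next power of two first, after which the periodized transform is exactly
orthonormal and per-direction energy is conserved to machine precision
(asserted at 1e-8 relative). The per-direction coefficient count is the
padded length, not p; the concatenated (approximation, detail_L, ...,
detail_1) rows form the `flat_view` grid consumed by the features.

## Pixel-intensity features

For a real matrix R with C1 rows, C2 columns and 1-based indices:

    PIF = sum R(i,j)^2                / (C1^2 C2^2)
    PVF = [sum (R-i)^2 + sum (R-j)^2] / (C1 C2)
    PMF = sum R(i,j)                  / (C1 C2)
    FIF = sum R(i,j) i j              / ((C1+1)(C2+1))
    SIF = sum R(i,j) i^2 j^2          / ((C1+1)^2 (C2+1)^2)

The index symbols in the denominators are evaluated at the matrix extents,
the only reading that makes each formula a single scalar statistic. PVF
mixes coefficient values with raw indices and is therefore
orientation-sensitive; rows are directions, columns coefficient indices,
throughout. All five implementations are checked against an independent
double-loop evaluation at 1e-12.

Because the classifier begins with convolutions but the method feeds it
"features", the classifier input is a 5-channel *blockwise feature map*:
each feature evaluated on sliding block x block windows of `flat_view`
(defaults block 8, stride 4). The five global scalars are additionally
appended to the final embedding.

## Hybrid CNN + SFCM classifier

Architecture: two valid convolutions with ReLU (defaults 512 filters of 5x5
and 1024 of 7x7, stride 1 — "5x5 stride function" is read as kernel size,
since stride-5 on these inputs would be degenerate) interleaved with two
non-overlapping pooling layers (max, size 2), then a linear bottleneck
embedding (default 16-d), and a two-cluster fuzzy c-means output layer
instead of a dense softmax.

Input conditioning: the coefficient grid has a fixed band structure spanning
about six orders of magnitude, identical in every image. Each (channel, row,
column) cell of the feature maps is therefore z-scored across the training
batch (statistics frozen into the model), so the network sees the per-image
anomaly signal on a well-conditioned scale.

Training is two-stage and fully deterministic given the seed:

1. **Supervised pretraining.** A temporary 2-way softmax head is attached to
   the bottleneck and the whole stack is trained with cross-entropy plus a
   center loss (weight 0.1) under Adam (lr 1e-3, 12 epochs, batch 16). The
   center loss pulls same-class embeddings toward running class centers;
   cross-entropy alone produces a separating hyperplane but loose clusters,
   and the unsupervised clustering of stage 2 then splits along nuisance
   directions (observed cluster/label agreement 0.64–0.78 without center
   loss, 1.00 with it).
2. **SFCM output layer.** The head is discarded, embeddings are re-extracted
   and standardized, fuzzy c-means (m = 2) clusters them into two groups, and
   each cluster is mapped to the training label in majority agreement.
   Classification of a new slice computes its membership against the frozen
   centroids; ties break toward the lower cluster index.

The SFCM update alternates standard FCM membership/centroid steps; when grid
positions are supplied, memberships are re-weighted by u' ~ u^p h^q with h
the sum of neighbours' memberships in the Moore neighbourhood (radius 1 by
default) and renormalised — the dominant published meaning of "spatial FCM".
With p = 1, q = 0 (or without positions) the procedure is plain FCM, an
identity the tests assert at 1e-9. The FCM objective trace is non-increasing
for plain FCM. Per-image classification uses embeddings without grid
positions; the spatial step matters when clustering per-pixel or per-cell
maps.

An alternative `train_filters="random"` mode skips stage 1 (fixed random
filters) for ablation of the supervised pretraining.

Filter counts 512/1024 are the method's stated architecture and remain the
config defaults; the benchmarks in this repository run 16/32, which train in tens
of seconds on one CPU and already saturate the phantom task. Accuracy
contracts in the tests are stated at that reduced scale.

## Probability-based morphological segmentation

For a slice M, with a flat disk structuring element (radius 3 default):

    M_o = open(M), M_c = close(M)
    p1 = pdf(M_o), p2 = pdf(M_c)      per-pixel intensity-probability maps
    A_t = (p1 + p2) / 2
    P_open = M_o / A_t, P_close = M_c / A_t
    M_diff = |P_open - P_close|

`pdf` is the normalised 256-bin intensity histogram read back per pixel, the
only reading under which all six steps compose on same-shaped grids.
Real-valued opened/closed images are rounded to integer bins for the lookup
only. A pixel of a rare intensity population with local morphological
texture — a compact dark tumor — gets a small denominator and a large
|open - close| numerator simultaneously, which is the detection principle.

The core method stops at M_diff; the binarisation is this package's own and was designed against the phantom benchmark's failure modes:

- **Quantization gate.** Pixels where |M_o - M_c| < 5 intensity levels are
  zeroed. Smooth large-scale gradients (skull rim, fade to air) produce
  sub-quantization morphological residues whose rarity-amplified responses
  are artefacts, not texture. The floor is half the default texture sd;
  configurable (`delta_floor`).
- **Despeckle.** Disk(2) median filter on the response map. Responses are
  pixel-wise noisy; the tumor is the only spatially coherent high-response
  region, and isolated rare-intensity pixels otherwise survive any global
  threshold.
- **Threshold.** The responses are ratio-scaled and span decades, with a
  large background class and a small tumor class — the unbalanced
  heavy-tailed regime where a global Otsu cut lands in the outlier tail
  (measured: an oracle threshold sweep on raw responses caps mean Dice near
  0.77; Otsu itself reached ~0). A two-component Gaussian mixture is fitted
  to log-responses and the cut placed where the high component's posterior
  reaches 0.5, falling back to log-domain Otsu when the posterior never
  crosses (very large tumors whose responses form one broad mode).
  Deterministic via fixed quantile initialisation.
- **Cleanup.** Hole filling, then removal of connected components smaller
  than `min_area` (30 px default).

A response map that is already two-valued short-circuits to an exact
half-value cut, so ideal inputs are recovered pixel-perfectly. On the
phantom benchmark (50 slices, size 128, disk tumors radius 8–20, element
radius 3, min_area 30) the segmenter attains mean Dice 0.91–0.93 and median
0.92–0.94 across independent master seeds.

## Evaluation metrics

Pixel (or image) confusion counts use the A/B/C/D naming: A true negatives,
B false positives, C false negatives, D true positives. Two conventions are
reported side by side because the published formula set conflicts with its
own symbol glossary: `standard` (specificity A/(A+B), accuracy (A+D)/total,
precision D/(B+D), FPR B/(A+B)) is the default and the recommended one; `paper_literal` evaluates the
printed formulas verbatim (specificity B/(A+B), accuracy (B+D)/total,
precision A/(A+C), TPR and FPR both printed as A/(A+D)) so the divergence is
auditable. Metrics with zero denominators are reported as explicit nulls,
never imputed as zero. Dice = 2D/(2D+B+C).

## Phantom generator

Each phantom is a 128 x 128 8-bit slice with black air, a bright skull
annulus, noisy parenchyma (mean 120, texture sd 10) and, for the positive
class, one compact blob drawn from the tumor intensity band [60, 95) — below
the parenchyma by at least 25 levels, emulating the lower signal of
meningioma on these sequences. Rendering choices that matter:

- The head ellipse (semi-axes 0.40/0.34 of the frame) fits fully inside the
  image including the fade ring; a ring clipped at the border creates
  spurious high-response arcs.
- Region transitions are smooth ramps several pixels wide (partial-volume
  blur); the skull annulus is a flat plateau at the band midpoint, wider
  than typical structuring elements, because a ridge-shaped annulus is
  clipped by opening and lights up the difference image.
- Parenchyma texture is spatially correlated (Gaussian kernel, 1.5 px) —
  tissue texture, not sensor noise; the tumor is filled with *uncorrelated*
  texture of the same sd (heterogeneous tumor matrix). Both fields are
  empirically zero-mean over their regions, so the nominal 25-level contrast
  holds in every instance.
- Tumors are disks (exact analytic masks); an `irregular` mode perturbs the
  boundary with seeded radial harmonics.
- Per-image seeds derive deterministically from the master seed; identical
  seeds reproduce byte-identical files.

The phantom emulates the intensity structure the method relies on (compact
dark textured blob, common-intensity background, bright rim). It does not
model MRI physics — no bias fields, Rician noise, partial-volume mixtures
beyond the smooth ramps, or anatomical variability — so passing benchmarks
demonstrate the pipeline's mechanics and internal consistency, not clinical
performance.

## Benchmark sizes and numerical choices

Benchmarks are sized for a single CPU: classification uses 100 slices per
class (half train, half test) at filter counts 16/32; segmentation uses 50
phantoms; the feature-ablation study uses a low-contrast variant (tumor
radius 4–9, band [95, 118)) where single features cannot saturate. Notable
numerical conventions: min–max rescale to 8 bits rounds half-up; FCM
distances are clamped at 1e-24 (exact-hit samples get crisp memberships);
A_t is clamped at 1e-12 before division; model archives fix zip member
timestamps so identical models are byte-identical.

## Known limitations

- In the original formulation each single feature is one scalar per image,
  a very weak classifier input; here each single feature receives a full
  blockwise map, so single-feature models are far stronger. On
  the phantom benchmarks the five feature maps of the same blocks are
  strongly correlated, and the best single feature (PIF or PVF) matches or
  slightly exceeds the full set — measured across seed-averaged runs,
  harder variants, heterogeneous tumor presentations and doubled training
  sets; duplicating a single channel five times costs nothing, so the
  deficit is the mixing of correlated heterogeneous channels, not channel
  count. The qualitative "more features is never worse" ordering should
  therefore not be expected from this architecture on map inputs, and the
  ablation test records this as an open failure rather than papering over
  it.
- The FPR formula of the source is unrecoverable (printed identically to
  TPR); standard FPR is used under the `standard` convention.
- Segmentation assumes one compact tumor darker than its surroundings;
  multi-focal or hyperintense lesions are out of scope.
- 3-D volumes are reduced to a single axial slice on load (index 0 by
  default, configurable).
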