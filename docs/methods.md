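# Methods

This note documents the models, algorithms and numerical choices behind
`spinequant`, module by module, including the places where the design was
genuinely open and what the synthetic tests do and do not demonstrate.

## Coordinate conventions

Volumes are arrays indexed `(z, y, x)`; physical coordinates are µm with
the center of voxel `(k, j, i)` at `((i+0.5)·sx, (j+0.5)·sy, (k+0.5)·sz)`
for voxel size `(sx, sy, sz)`. All distance computations (rasterization,
clustering radii, ROI growth caps, dendrite gating) are carried out in µm
so anisotropic sampling — typically ~0.1 µm in xy versus 0.5 µm in z for
two-photon stacks — is handled uniformly. SWC tracings are interpreted as
µm by default (the NeuTube convention); a `unit_scale_um` factor converts
pixel-unit files.

## Segmentation network

A U-Net-style encoder-decoder with two decoders. The encoder has `D`
stages (default 4); stage `s` is a residual block mapping to `F·2^s`
channels — two (3×3 conv → batch norm → swish) layers with an identity
shortcut, 1×1-projected when channel counts change — followed by 2×2 max
pooling. The deepest feature map (the latent space, `F·2^D` channels) is
shared by two structurally identical decoders, one per target class. Each
decoder stage does parameter-free 2× nearest-neighbor upsampling,
concatenates the matching-scale encoder features (skip connection), and
applies one conv-BN-swish. The two heads end in a 3×3 convolution to one
channel with a logistic output, so both maps are probabilities in [0, 1].
Upsampling + convolution is used instead of transposed convolution to
avoid checkerboard artifacts. Batch norm precedes every activation but is
not applied before the final logistic.

Activations: hidden layers use swish `x·σ(x)`; the output layers use the
standard logistic `σ(x) = 1/(1+e^(−x))`. (A sign slip sometimes renders
these with a minus in the denominator; that form has a pole at 0 and is
not a probability, so the standard definitions are implemented.)

Open details resolved here: the exact number of convolutions per block
and the channel progression are not fully constrained by the published
architecture diagrams; the defaults above (two convs per encoder block,
one per decoder stage, per-stage filter doubling from `F ∈ {8,16,32}`)
are documented choices, configurable via `ArchitectureConfig`.

### Losses

The dendrite head is trained with the soft Dice loss
`L = 1 − (2·Σŷᵢyᵢ + ε)/(Σŷᵢ² + Σyᵢ² + ε)` (ε = 10⁻⁷ guards empty tiles
and makes empty-vs-empty score 0), the spine head with mean squared error
(mean over pixels, so the loss is tile-size invariant although the
original statement of the loss is a plain sum). The two losses are never
combined into one scalar objective with tuned weights: by default their
gradients are summed with unit weights each step; a config switch
(`loss_mode="alternate"`) instead alternates strict per-loss updates.
Both honor the intent of optimizing the targets separately; the summed
form is stabler in small-batch regimes.

### numpy engine

No deep-learning framework is part of the dependency set; the network
runs on a compact reverse-mode autodiff engine (`_nn.py`): im2col 3×3
convolution, 2×2 max pool, nearest-neighbor upsample, concat, batch norm
(momentum 0.9, ε = 10⁻⁵, running statistics for deterministic
evaluation), swish/logistic, Dice/MSE loss nodes, and Adam
(β₁ = 0.9, β₂ = 0.999). Gradients are verified against central finite
differences to ~10⁻⁸ relative error in the test suite. Everything is
float64 and deterministic given seeds, including across BLAS thread
counts at the sizes used here.

## Training pipeline

Tiles are sampled uniformly over (stack, plane, window) — no
foreground-biased sampling — normalized per tile to [−1, 1] (min → −1,
max → +1; constant tiles map to 0), and augmented on the fly: random
flips, 90° rotations, small rotations in ±10° (bilinear for the image,
nearest-neighbor + re-binarization at 0.5 for the masks), Gaussian noise,
brightness and contrast jitter (image only). Geometric transforms are
applied identically to image and targets. Stacks smaller than the tile
are reflect-padded.

Resolution handling mirrors the two published training regimes: `fixed`
mode resamples every stack to a single target pixel pitch (default
0.094 µm/px) before windowing; `mixed` mode streams native resolutions
(the training-data pool spans 0.0212–0.1245 µm/px). Both modes are
implemented and exercised; the comparative claim that mixed-resolution
training generalizes better across rescaled test data is not asserted in
the default test suite, as it requires two full training runs and the
margin is seed-noisy at desk scale.

The learning-rate schedule holds lr₀ = 0.5·10⁻³ for 15 warm epochs, then
decays as `lr₀·exp(−0.1·(epoch−15))`. The decay constant is read as a
rate per epoch: a literal time constant of 0.1 epochs would collapse the
learning rate to ~0 within a single epoch. Epoch length defaults to
⌈candidate tiles / batch⌉ with a config override, since streamed sampling
has no natural epoch. Batch size (32) and epoch count (50) are config
defaults, not claims. Divergence (non-finite loss) aborts with a
diagnostic. The best checkpoint (lowest combined loss) is kept.

## Inference and post-processing

Prediction is strictly per-plane: each z-plane is normalized, reflect-
padded to a multiple of `2^D`, passed through the network in evaluation
mode and cropped back, so output geometry always equals input geometry
and permuting planes permutes outputs. Optionally planes are resampled to
the model's training pixel pitch and the maps resampled back.

Post-processing follows two steps, both idempotent and optional:

1. **Dendrite cleanup** — binarize the dendrite map (default 0.5), drop
   per-plane 8-connected components under `min_size_2d` (default 10 px)
   and 3D 26-connected components under `min_size_3d` (default 50 vox),
   zeroing the removed probabilities.
2. **Spine gating** — dilate the cleaned dendrite mask by a physical
   radius (default 1 µm, ellipsoid structuring element scaled per axis)
   and zero spine probability outside it: an implicit maximum
   distance-to-dendrite criterion.

Connectivity conventions (26-neighborhood in 3D, 8 in 2D) and all
thresholds are config values; the published method leaves the numeric
sizes to the user.

## ROI extraction

Two builders, identical acceptance filters:

* **Flood fill** — seeds are unvisited voxels above `seed_threshold`
  (default 0.25), visited in strictly decreasing probability with
  (z, y, x) tie-breaks for determinism. A region grows over 26-neighbors
  whose probability is at least ρ·(seed probability) (the "relation to
  seed", default ρ = 0.5) within a physical distance cap of the seed
  (default 3 µm). Visited marking makes ROIs disjoint. Note one
  consequence: with ρ·peak above the seed threshold, the annular remainder
  of a blob can seed secondary ROIs — these fall to the size filter, or
  can be avoided by choosing ρ ≤ seed_threshold/peak.
* **Connected components** — binarize at `area_threshold` (default 0.25)
  and take each 3D 26-connected component.

Filters: voxel count within [10, 10 000], minimum plane span, and an
explicit maximum distance to the nearest dendrite voxel (anisotropic
EDT) when not already gated implicitly. The default minimum plane span
is 1: at 0.5 µm z-steps a ~1 µm spine head frequently occupies a single
plane of the per-plane prediction maps, so requiring ≥2 planes
systematically discards correctly detected spines; users with finer z
sampling should raise it. 2D mode runs the same algorithms per plane
with the span filter disabled. ROI label volumes resolve overlaps by ROI
order (first wins). ImageJ export writes one freehand outline record per
occupied plane (per 4-connected in-plane part), with the slice index in
the record and a shared name prefix per ROI; outlines are exact pixel-
boundary polygons, so every exported pixel center lies inside its
polygon.

## Multi-rater clustering and reliability

Pooled spine-center annotations are grouped into per-spine clusters:

1. DBSCAN on coordinates scaled by (r_xy, r_xy, r_z) = (0.85, 0.85,
   2.5) µm with eps = 1 and min_samples = 1 — scaling makes the two
   published radii a single dimensionless radius, and min_samples = 1
   keeps single-rater annotations as clusters (the cluster-size
   histogram counts spines found by exactly one rater, so no annotation
   may vanish). The exact density-clustering settings are not published;
   reproduced statistics may shift by a percentage point or two.
2. Adjustment passes: (i) eject members farther than the per-axis radii
   from their cluster centroid (one at a time, centroid recomputed;
   ejected points become singletons); (ii) split clusters exceeding the
   member cap (default 7 = the rater count) by 2-means seeded at the two
   most mutually distant members, repeated until no cluster exceeds the
   cap; (iii) greedily merge cluster pairs, closest first, whose
   centroids are within the radii and whose union respects the cap.
   A final ejection sweep restores the per-axis membership radii that
   merging can disturb. Deterministic given the params seed.

Pairwise recall (A, B) = |clusters with both| / |clusters with A|, a
rater counting once per cluster regardless of duplicate members.
Inter-rater reliability is the mean ± sd of the off-diagonal recall
entries. Intra-rater reliability clusters each rater's two annotation
rounds separately — pooling all raters' rounds would exceed the member
cap and split true clusters — and averages the two-way recall between
rounds. Algorithm outputs (ROI centroids) enter as one more rater label.
Mask agreement uses IoU, defined as 1 for two empty masks; rater masks
combine voxelwise (intersection/union).

One measured boundary: under the synthetic rater model, cluster count
recovers the true spine count exactly for annotation jitter ≤ 0.25 µm
(sd, xy), but at 0.3 µm jitter the ejection radius necessarily strands
jitter-tail annotations as extra singleton clusters (~10% overcount).
This is a property of the published adjustment rules, not an
implementation artifact; the recovery tests therefore run at ≤ 0.25 µm.

## Fluorescence quantification

Traces are per-frame means over ROI voxels; ΔF/F₀(t) = (F(t) − F₀)/F₀
with F₀ the mean over user-chosen baseline frames (the conventional
choice is 20 event-free frames — an expert judgment, so indices are
user-supplied; an automatic lowest-mean-window rule is provided but off
by default). RSDR compares a spine ROI's maturity/structure intensity
ratio with that of the entire dendrite mask in the field of view; values
above 1 indicate spine enrichment of the maturity marker. Trace
agreement is Pearson r, optionally after a centered moving average
(default width 9) with truncated windows at the edges. ΔF/F₀ is
invariant to multiplicative gain and RSDR to global rescaling of either
channel; both invariances are tested.

## Synthetic data

Scenes emulate the package's primary imaging regime — two-photon stacks
of dendrites at 94 nm xy / 0.5 µm z: one or more smooth tubes (sinusoidal
low-order curves, radius 0.5 µm) rasterized as capsule chains, decorated
with spines whose heads (radius 0.4–0.6 µm, mature mushroom-type scale —
chosen so heads span >1 z-plane at 0.5 µm steps) sit on thin necks
(radius 0.12 µm, length 0.4–1 µm) protruding mostly in-plane. Placement
is rejection-sampled to keep head centers > 2·max radius apart, so the
spine mask has exactly one 26-connected component per spine and spine
and dendrite labels are disjoint (necks belong to the spine class).
Rendering: baseline 10 + amplitude 200 per labeled voxel, anisotropic
Gaussian PSF (σ = 0.1/0.1/0.35 µm), shot-like noise approximated as
Gaussian with variance ∝ intensity (matching the first two moments of
Poisson noise at desk speed; exact Poisson is deliberately not used) and
read noise (σ = 4). Everything is reproducible from the scene seed.

Simulated raters detect each spine with probability p (constant or a
function of the spine center), jitter annotations with anisotropic
Gaussian noise, and add Poisson-count false positives placed ≥ 1 µm from
any true structure so tests can identify them unambiguously.

What passing synthetic tests shows: the pipeline's algorithms are
internally consistent, the network can learn and generalize within this
scene family, and the statistics behave as designed under a known ground
truth. What it does not show: performance on real microscopy, whose
structured background (crossing neurites, depth-dependent contrast,
motion artifacts, spine-shape diversity) the generator deliberately does
not model.

## Scaled-down study sizes

Tests and the acceptance script use desk-scale problem sizes chosen as
the package's own defaults: scenes of 96×96×10 voxels with 5 spines;
end-to-end runs train an F=8, depth-3 network on 48 px tiles for 24
epochs × 70 steps (batch 8, lr₀ 3·10⁻³ under the flat-then-exponential
schedule, so the last nine epochs run at decayed rates and the losses
settle) on 20 scenes and evaluate 10 held-out scenes. Under these
conditions the held-out thresholded spine IoU is ~0.84 and the default
ROI pipeline recovers the true spine count within ±1 on ≥8/10 stacks;
the residual extra ROIs are low-confidence components (mean probability
well below 0.5) — the liberal end of the threshold trade-off, which a
higher `area_threshold` suppresses.
The overfit sanity check (8 fixed tiles, 200 Adam steps) drives the
combined loss to < 1% of its initial value. Statistical checks
(recall ≈ detection probability, cluster-count recovery, RSDR ≈ built
enrichment within PSF-mixing tolerance of ~12%) use 20–50 Monte-Carlo
seeds.

## Known limitations

* Per-plane (2D) prediction: no 3D convolutions; z-context enters only
  through ROI building.
* The numpy engine is single-threaded and desk-scale; it is not meant
  for 10⁵-step GPU training schedules.
* Clustering statistics depend mildly on the unpublished density-
  clustering settings (see above).
* The ImageJ export writes filled outlines; interior holes of an ROI
  plane are not represented.
* Flood-fill ROIs depend on the seed-relation parameter ρ; the published
  description names the parameter but not its value.
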