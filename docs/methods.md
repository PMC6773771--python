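# Methods

This note documents the modeling and numerical choices behind `histopatch`:
what the pipeline assumes, which knobs matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Problem setting and assumptions

The target task is *regional* cancer detection on H&E whole-slide images:
ground truth is a hand-outlined cancer area, not cell-level annotation, so
the unit of prediction is a 101×101-pixel patch labeled by its center pixel
at ~0.92 um/px (4× nearest-neighbour downsample of a 0.23 um/px scan).
Patch classification plus overlap-averaged reconstruction is preferred over
fully-convolutional segmentation because the tissue consists of large
single-class regions with relatively few border patches, and coarse ground
truth would punish correct fine-grained segmentations.

Key geometric facts, all verified by tests: the stem maps 101 → 99 → 97 →
48 → 23 (valid 3×3 convs, one 2×2/2 max-pool, one 3×3/2 conv); tiling at
stride 50 overlaps adjacent patches by 51 pixels; the heat-map block is
50×50 pixels with 4 contributing patches in the interior; a 101-pixel patch
spans ~92 um.

## Architecture

The classifier is Inception-V4 with a shortened stem. Block anatomy
(branch structure and full-width channel counts) follows the canonical
Inception-V4 publication; the block-level output widths (Inception-A 384,
Reduction-A 1024, Inception-B 1024, Reduction-B 1536, Inception-C 1536)
match the published schematic of the modified network. With repeats
(4, 7, 3) the network contains exactly 141 convolutions and 18 pooling
layers; `count_layers` gives the closed form

    n_conv = 3 + 7·n_a + 4 + 10·n_b + 6 + 10·n_c
    n_pool = 4 + n_a + n_b + n_c

and is cross-checked against a walk over the instantiated graph.

Two printed details of the source schematic are internally inconsistent and
were resolved as follows:

- a first-conv output of "98×98" is impossible for a valid 3×3 on 101
  (which gives 99); we implement valid 3×3, and every later row of the
  schematic re-converges (48×48, 23×23, 11×11, 5×5);
- the middle-stack row is read as **7** Inception-B blocks — the only
  count that reproduces both printed totals (141 and 18).

**Activation.** The schematic's caption states sigmoid activation with 40%
dropout on all convolutions. A 141-layer sigmoid network without
normalization layers is effectively untrainable, and per-convolution 40%
dropout even more so; we default to ReLU (He initialization) with a single
dropout (rate 0.40) before the linear head, and expose
`activation="sigmoid"` (Xavier initialization) for fidelity experiments
rather than silently choosing.

**Miniatures.** `width_multiplier` rescales every channel count
(`ceil`, minimum 1) and the repeat counts are free, so an architecturally
identical miniature (width 0.125, repeats 1/1/1 — 40 convs) trains on one
CPU in minutes. Layer-count introspection always supports the full
configuration without training it.

**Softmax.** The printed training objective normalizes e^{F(I_k)} over the
batch index, which cannot be the intended per-patch two-class softmax (F is
typed as a scalar map); we implement the standard per-patch softmax over
two logits. Similarly the printed cost function pairs the cancer-positive
indicator with log(1−p); since the accompanying text specifies softmax
cross-entropy, we pair g^P with log p. Both readings are recorded here
rather than silently fixed.

## Training

Adadelta (ρ = 0.95, ε = 1e-6) at learning rate 1.0, decayed by 0.95 every 3
epochs (`lr = decay^⌊epoch/3⌋`); batch size 128; patches converted
RGB → HSV before entering the network. Per epoch each training patch gets
one uniformly random dihedral orientation and one jitter draw: hue shifted
additively (circular, modulo 1), saturation and brightness scaled by
(1 + u) with u per channel, contrast rescaling brightness about its patch
mean, saturation/brightness clipped to [0, 1]. The percent semantics
(additive hue, multiplicative S/V, mean-anchored contrast) are our fixed
reading of the published percentages; contrast acts on brightness only,
since contrast is an intensity notion. Jitter presets: scc
(4/15/8/2%), thyroid (5/5/8/5%), lymph_node (10/10/10/10%); epoch budgets
30/70/20.

"Optimal number of training epochs" is operationalized as
best-validation-AUC checkpointing (the published metric of record is AUC).
An epoch is one pass over the sampled, capped, balanced patch set. No
gradient clipping. Everything is seeded (sampling, orientation/jitter
draws, weight init, data order, dropout); with single-threaded numpy a
repeat run is bit-identical. Training and validation sets must be
slide-disjoint; `fit` enforces this and never lets a validation patch touch
a gradient.

## Inference and reconstruction

Test-time augmentation averages the 8 dihedral orientations, each with an
independent jitter draw seeded per (slide, origin, orientation) so
heat-maps are reproducible; a no-jitter mode exists for deterministic
tests. Block incidence is geometric: block (u, v) averages every patch
whose footprint fully contains it. This reproduces the intended
4-contributor interior average and the free-edge behavior, and is verified
exactly against a brute-force enumeration; the printed index arithmetic
(offsets of 49 against a stride of 50) is internally inconsistent, so the
geometric rule is our recorded interpretation.

**Background masking.** Tiles failing the tissue filter (mean saturation
< 0.05 or mean brightness > 0.95 over the footprint) are assigned
probability 0 without evaluating the model. The network never sees
non-tissue during training, so its outputs there are undefined; masking is
standard WSI practice and keeps the slide-level maximum-probability score
meaningful. It is switchable (`tissue_mask=False`) for slides without
background.

## Evaluation

Patch-level AUC pools all test patches; slide-level diagnosis assigns each
slide its maximum patch probability, with a slide positive when its mask
contains any cancer. The operating threshold maximizes Youden's J on the
validation split (the published account names no criterion; J is the
standard ROC-optimal cut), ties breaking toward the higher threshold, and
is applied strictly (`score > t`, matching "probability of greater than
62%"). Bootstrap intervals (default 1000 replicates, percentile 2.5/97.5)
resample *slides*, not patches — patches within a slide are spatially
correlated, so the slide is the conservative unit; replicates that lose a
class are redrawn up to 10 times, then dropped with a logged count.
Undefined ratios (empty denominators) are reported as NaN with a warning,
never silently as 0.

## Grad-CAM

Canonical grad-CAM at the last stem convolution (the stride-2 conv before
the Inception stack): channel weights are the spatial mean of the class
logit's gradient, the map is the rectified weighted activation sum,
bilinearly upsampled to 101×101 and max-normalized per class
(identically-zero maps are returned flagged rather than renormalized). The
tracing runs in float64 so the map matches the closed-form solution of a
one-layer model to better than 1e-6.

## Synthetic data: what it does and does not emulate

The generator produces, per patient, a tumor slide (cancer ≈ 90% of
tissue), a normal slide and a tumor–normal interface slide (≈ 50%), with a
congruent binary mask, on a near-white background (all channels ≥ ~0.92).
Normal tissue is an eosin-pink base with sparse large stamped elliptical
nuclei; cancer is hematoxylin-purple with dense small nuclei; both carry
low-amplitude filtered-noise texture. Each slide receives a global stain
shift drawn uniformly (hue ±0.02, saturation ±10%, brightness ±5%),
emulating between-slide staining variability; an optional fraction of the
area is Gaussian-blurred to mimic out-of-focus artifacts. Large smooth
random fields are synthesized on a decimated grid and bilinearly upsampled
(identical character, much cheaper). Splits are patient-disjoint with
randomized assignment under the cohort seed; identical (spec, seed) gives
bit-identical output.

Cancer regions are carved from a smoothed noise field plus a strong
directional gradient, producing *low-curvature* margins. This matches the
regional character of the real annotations (large single-class areas, few
border patches) and is deliberate: with high-curvature margins a large
share of patch centers sit within a few pixels of the class boundary, where
the center-pixel label is irreducibly ambiguous at patch scale.

What passing the end-to-end test therefore shows: the pipeline can learn a
texture/color distinction under per-slide stain shifts and recover the
spatial extent of the marked region through the full
tile–TTA–reconstruct–threshold chain, on patients never seen in training.
What it does not show: robustness to real H&E variability (nuclear
pleomorphism, inflammation, processing artifacts, scanner differences) or
performance at clinical effect sizes — the generator's classes are
separable by construction (circular hue margin > 0.05 between cancer and
normal tissue, asserted by test).

## Study sizes for the end-to-end check

10 patients (30 slides of 1024², i.e. 256² at working resolution; 6/2/2
patients across train/validation/test), per-slide training caps of 250
cancer + 250 normal patches (≈ 3000 patches, balanced), 50 + 50 per slide
for validation/test sets, the width-0.125 / repeats-1/1/1 miniature, 5
epochs. These sizes are the package's chosen desk-scale study conditions;
on them the miniature reaches validation AUC ≈ 0.98, held-out patch AUC
≈ 0.98, slide-level AUC 1.0 and heat-map Dice ≈ 0.83 against the true
masks (seeded, reproduced by `tests/test_acceptance.py`).

## Numerical choices and degenerate inputs

- The autodiff engine is float32; convolutions are im2col GEMMs over
  bounded batch chunks; max-pool gradients go to every element equal to the
  window maximum (exact ties have measure zero for continuous
  activations); average pooling divides by the full kernel size including
  padding.
- Cross-entropy floors log arguments at 1e-12, so confident wrong
  predictions yield large finite loss.
- Nearest-neighbour downsampling takes input pixel (i·f, j·f) for output
  (i, j) — anchor at the top-left sample, chosen (and stated) because the
  source does not specify the sample point; composition
  (a then b = a·b) holds exactly under this convention.
- Heat-maps serialize as 16-bit PNG (probability × 65535, round half up):
  round-trip error ≤ 1/65535; out-of-range probabilities are rejected
  before any file is written.
- Slides smaller than 202×202 are rejected by the generator (no stride-50
  grid); slides smaller than one patch are skipped by the sampler with a
  warning and rejected by the tiler with an error.
- Single-class inputs to AUC or threshold selection raise errors naming the
  missing class.

## Known limitations

- Nuclei are stamps, not segmentable objects; no nuclei-level ground truth.
- No stain normalization or color deconvolution (variation is handled by
  augmentation, mirroring the source method).
- Pyramidal WSI formats are not read natively; an adapter can be slotted
  behind `load_pair`.
- The full-width network is instantiable and countable but not trainable at
  desk scale; training claims are made only for miniatures.
- Bootstrap replicate count and unit, the epoch-selection metric, and the
  Youden-J threshold rule are documented choices where the source is
  silent.
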