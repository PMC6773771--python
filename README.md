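# histopatch

Patch-based convolutional detection and localization of cancer in digitized
whole-slide histology images (WSIs), with a bundled synthetic
pseudo-histology generator so that the entire pipeline — patch sampling,
training, heat-map reconstruction, evaluation and explanation — is testable
end to end on a desktop without clinical data.

## Who this is for

Researchers building regional (not cell-level) cancer-detection pipelines on
H&E-stained slides: surgical-margin assessment, slide triage, or method
studies on patch-classification design choices (color spaces, test-time
augmentation, overlap averaging).

## The method

A slide and its binary cancer annotation are downsampled 4x with
nearest-neighbour interpolation (0.23 um/px → ~0.92 um/px, so a patch spans
roughly 92 um of tissue). Patches **I** ∈ ℝ^(101×101×3) are labeled by
their *center pixel* against the mask. Training patches come only from
tumor and normal slides, capped per slide ("up to 5000 cancer / 1000 normal
patches per slide" in the lymph-node recipe) and approximately balanced
between classes.

The classifier is a modified Inception-V4: a shortened stem of three valid
3×3 convolutions and one 2×2 max-pool (spatial trace 101 → 99 → 97 → 48 →
23) followed by the canonical stack of 4 Inception-A, Reduction-A,
7 Inception-B, Reduction-B and 3 Inception-C blocks, global average
pooling, dropout, and a 2-class softmax head — 141 convolutional layers and
18 pooling layers in total. Batches are converted RGB → HSV before entering
the network; training minimizes the mean two-class cross-entropy

L = −(1/K) Σₖ [gₖᴾ log pₖ + gₖᴺ log(1 − pₖ)]

with Adadelta at learning rate 1.0, decayed by 0.95 every 3 epochs, batch
size 128. Each training patch receives one random dihedral orientation (of
the 8 symmetries of the square) and an HSV/contrast jitter draw per epoch;
the epoch count is selected on validation AUC.

At inference a slide is tiled at stride 50 (51-pixel overlap). Each tile is
classified in all 8 orientations with independent jitter and averaged,
p̄ = (1/8) Σₛ pₛ; overlapping tile predictions are then averaged per
50×50-pixel block (4 contributors in the interior, fewer on free edges),
giving a heat-map at 50-pixel detail. A slide's diagnosis score is the
maximum p̄ over its tiles. The operating threshold is chosen on the
validation split by maximizing Youden's J and applied with the strict rule
*score > threshold*; metrics (AUC, F1, accuracy, sensitivity, specificity)
carry percentile bootstrap confidence intervals resampled over slides.
Grad-CAM maps traced from the last stem convolution to either class logit
visualize the evidence behind individual patch calls.

The network and its training loop run on a small numpy reverse-mode
autodiff engine included in the package (`histopatch._autodiff`); a
`width_multiplier` rescales every channel count so architecturally
identical miniatures train on one CPU in minutes.

## Worked example

```python
import dataclasses
from histopatch import (
    SamplingPolicy, ModelConfig, TrainConfig, JitterProfile,
    generate_cohort, build_model, fit, sample_training_patches,
    sample_patches, predict_patches, predict_slide, roc_auc, select_threshold,
)
from histopatch import slide_io, patch_sampler

manifest = generate_cohort(10, (1024, 1024), (0.6, 0.2, 0.2), seed=7,
                           out_dir="cohort")
pairs = list(slide_io.load_cohort(manifest, 4))      # 4x downsample -> 256x256
policy = SamplingPolicy(max_cancer_per_slide=250, max_normal_per_slide=250, seed=7)
eval_policy = dataclasses.replace(policy, roles_included=("tumor", "normal", "interface"),
                                  balance=False, max_cancer_per_slide=50,
                                  max_normal_per_slide=50, seed=8)
split = {s: [(sl, m) for sl, m in pairs if sl.split == s]
         for s in ("train", "validation", "test")}
train_ps = sample_training_patches(split["train"], policy)
val_ps = sample_patches(split["validation"], eval_policy)

model = build_model(ModelConfig(n_inception_a=1, n_inception_b=1,
                                n_inception_c=1, width_multiplier=0.125), seed=0)
model, history = fit(model, train_ps, val_ps,
                     TrainConfig(max_epochs=5, jitter=JitterProfile.preset("scc"), seed=0))
for r in history.records:
    print(f"epoch {r.epoch}: loss {r.train_loss:.3f}  val AUC {r.val_auc:.3f}  lr {r.lr:.3f}")

test_ps = sample_patches(split["test"], eval_policy)
print("test patch AUC:", round(roc_auc(predict_patches(model, test_ps), test_ps.labels), 3))
```

Output from this exact run (seeded, single-threaded):

```
epoch 0: loss 0.687  val AUC 0.976  lr 1.000
epoch 1: loss 0.452  val AUC 0.977  lr 1.000
epoch 2: loss 0.345  val AUC 0.977  lr 1.000
epoch 3: loss 0.202  val AUC 0.979  lr 0.950
epoch 4: loss 0.145  val AUC 0.984  lr 0.950
test patch AUC: 0.984
```

The loss falls as the miniature network learns to separate the
hematoxylin-purple, dense-nuclei cancer texture from the eosin-pink normal
texture; validation AUC near 1 means held-out patches from unseen patients
are ranked almost perfectly, and the remaining errors sit at annotation
boundaries where the center-pixel label is genuinely ambiguous. On the same
run, slide-level diagnosis (max patch probability vs "mask contains any
cancer") reaches AUC 1.0 and the thresholded heat-maps overlap the true
masks with Dice ≈ 0.83.

The same pipeline is scriptable from a shell:

```bash
histopatch simulate --config cfg.yaml --out cohort
histopatch train    --config cfg.yaml --manifest cohort/manifest.csv --out run
histopatch evaluate --config cfg.yaml --manifest cohort/manifest.csv \
                    --checkpoint run/model.npz --out eval
histopatch audit    # prints the 141/18 layer counts of the full network
```

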