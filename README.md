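# grainsight

Identifying rice varieties from images of individual kernels is a
standard quality-control task in grain trading: varieties differ subtly
in kernel size, shape and surface texture, and manual inspection does
not scale. `grainsight` implements a two-stage identification pipeline
for researchers and engineers working on grain (or other seed) imagery:

1. **Saliency-based segmentation.** Each image is over-segmented into
   SLIC superpixels; graph-based manifold ranking with the top, left and
   right border superpixels as background seeds, combined with a
   diffusion-compactness cue and a coarse-to-fine re-ranking pass,
   yields a saliency map `I₂` that is thresholded into a grain mask.
   Ranking solves `(I − αP)⁻¹ y` with `P = D⁻¹W` the normalized CIELAB
   affinity graph, `α = 0.99`.
2. **Feature fusion, selection, classification.** Features extracted
   from two backbone views (reference DarkNet19 / SqueezeNet
   architecture specs with a deterministic mock extractor for offline
   work) are fused by a maximum-correlation rule — near-duplicate
   columns (|r| ≥ 0.9) are deduplicated and columns uncorroborated by
   the other view (max |r| ≤ 0.05) dropped — then pruned by an improved
   butterfly optimization algorithm: canonical BOA moves (fragrance
   `f = c·Iᵃ`, global step `P += (rn²·b_p − P)·f`, local step
   `P += (rn²·P_k − P_l)·f`) hybridized with the cross-entropy method,
   which refits a Bernoulli distribution over subsets to the elite
   fraction each iteration (`a_{k+1} = α_s a⁺ + (1−α_s) a_k`). Subsets
   are scored by 5-NN cross-validated error plus a sparsity penalty.
   A panel of eleven classifiers (SVMs, k-NN variants, LDA, five MLP
   sizes) reports macro recall, precision, F1, FNR and accuracy.

A fully seeded synthetic-data module generates grain-like images with
ground-truth masks and labeled feature matrices with planted
informative / redundant / noise structure, so every stage is testable
without downloading data. See `docs/methods.md` for the models,
parameter defaults and design rationale.

## Worked example

Segment one synthetic grain image and check it against the known mask:

```python
from grainsight.synthetic import gen_grain_images
from grainsight.segmentation import segment_image, iou

sample = gen_grain_images(n_per_class=1, n_classes=5, hw=128, seed=0)[2]
res = segment_image(sample.image)
print(f"threshold={res.threshold:.3f} mask_px={int(res.mask.sum())} "
      f"IoU={iou(res.mask, sample.mask):.3f}")
```

```
threshold=0.259 mask_px=1376 IoU=0.994
```

The adaptive threshold (twice the mean saliency) lands at 0.259, the
mask covers 1376 pixels, and it overlaps the ground-truth ellipse at
IoU 0.994.

Run the whole pipeline on synthetic data from the command line:

```bash
grainsight run-all --synthetic --seed 1 --out runs/demo
```

The manifest it prints records the dimension accounting stage by stage:
200 images are segmented, two 128-dimensional feature views extracted,
fusion keeps 52 of 256 columns (the two mock views are heavily
redundant by construction), the selector keeps 4, and the classifier
table written to `runs/demo/results.csv` reports, e.g.:

```
classifier,recall,precision,f1,fnr,accuracy,...
linear_svm,100.0,100.0,100.0,0.0,100.0
quadratic_svm,100.0,100.0,100.0,0.0,100.0
cosine_knn,99.0,99.05,99.02,1.0,99.0
...
```

— macro recall/precision/F1/FNR and accuracy in percent for each panel
member on the stratified 50:50 holdout; FNR is identically
100 − macro recall. Individual stages are available as `grainsight
synth | segment | extract | fuse | select | classify`, all reading and
writing plain CSV/PNG/JSON.

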