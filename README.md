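# raclahe

Region-adaptive contrast-limited adaptive histogram equalization
(RACLAHE) for prostate MRI, together with the evaluation machinery
needed to compare histogram-based enhancement methods for zonal
segmentation: four comparator enhancers, six per-frame segmentation
metrics, inter-model aggregation with rank-sum significance flags,
saliency-vs-ground-truth explainability maps, and a seeded synthetic
phantom generator so the whole stack runs without any external data.

## The problem and the method

T2-weighted prostate MRI has low soft-tissue contrast between the
transitional zone (TZ) and the peripheral zone (PZ) of the gland, and
smooth coil-induced intensity inhomogeneity (bias field) on top.  Global
histogram remaps waste their dynamic range on the background; local
equalization amplifies background noise.  RACLAHE restricts local
enhancement to an automatically proposed square region Q that contains
the gland inside the frame Z (on 256×256 frames, Q covers roughly
0.25 ± 0.12 of the frame; the proposed side is clamped to 134 ± 15 px):

1. **Propose** Q from a detector — here a reference-mask oracle, a fixed
   centered square, or external JSON proposals.
2. **Enhance** the crop FM_Q patch-wise: for each patch with `TotNum`
   pixels and per-level counts `Num(i)`,

       P(i)   = Num(i) / TotNum
       CDF(i) = Σ_{k ≤ i} P(k)
       out(i) = round((L − 1) · CDF(i)),   L = 256 gray levels

   either literally per independent 8×8 patch (the default), or in the
   classic contrast-limited form (histogram clipping at
   `clip_limit · TotNum` with uniform redistribution, bilinear blending
   of tile mappings).
3. **Recombine**: `RACLAHE = FM_Q^trans + (FM_Z − FM_Q)` — every pixel
   outside Q is bit-identical to the input.

The comparator enhancers are global HE, CLAHE, AGCWD (per-level gamma
`1 − cdf_w(l)` from a weighting-distribution-transformed pdf), AGCCPF
(uniform-histogram blending before the same gamma stage) and RLBHE
(bi-histogram equalization split at the Otsu threshold, output ranges
chosen to preserve mean brightness).

Evaluation uses Dice, Sensitivity, balanced accuracy, Rand error index,
95% Hausdorff distance and average surface distance per frame;
method-level summaries are the mean and standard deviation of per-model
mean scores, min-max normalized per metric for display (reciprocals for
distances), and two-sided Wilcoxon rank-sum comparisons at p ≤ 0.05.
Explainability compares the pixel-wise density of a model's saliency
stack against the density of the ground-truth masks via their absolute
difference map and MSE.

## Worked example

`examples/segmentation_gain_demo.py` runs the full loop on 50 seeded
low-contrast phantom slices — propose the gland region from the
whole-gland mask, segment with a classical threshold baseline before and
after RACLAHE:

```
slices:            50
mean Dice, raw:    0.691
mean Dice, RACLAHE:0.826
gain:              +0.135
```

The phantom's bias field varies across the gland region, so one global
threshold inside the region misclassifies; region-adaptive local
equalization restores separability and recovers much of the lost
accuracy.  The other scripts in `examples/` each demonstrate one
capability (phantom generation, the five enhancers, the pipeline's
recombination identity, per-frame scoring, inter-model benchmarking,
explainability maps) and print a short interpretation of their numbers.

A thin CLI mirrors the library:

```sh
raclahe phantom --n-patients 3 --slices 5 --seed 42 --preset low-contrast --out cohort/
raclahe enhance --input cohort/P000_t2.nii.gz --output enh.nii.gz \
        --method raclahe --proposer mask --mask cohort/P000_wg.nii.gz
raclahe score --pred pred.nii.gz --gt cohort/P000_wg.nii.gz --out scores.csv
raclahe explain --gt cohort/P000_wg.nii.gz --saliency sal.nii.gz --report mse.json
```

## Layout

| module               | contents                                                  |
|----------------------|-----------------------------------------------------------|
| `raclahe.volio`      | NIfTI/PNG I/O, `Frame`/`Volume`/mask/saliency containers, gray-level quantization |
| `raclahe.enhance`    | per-patch equalization core; HE, CLAHE, AGCWD, AGCCPF, RLBHE |
| `raclahe.pipeline`   | region proposers, RACLAHE composition, patch counting     |
| `raclahe.seg_metrics`| Dice/Sensitivity/BA/REI, HD95/ASD                         |
| `raclahe.benchmark`  | score panels, inter-model aggregation, Wilcoxon flags, heatmaps |
| `raclahe.explain`    | density maps, absolute-difference map, density MSE        |
| `raclahe.phantom`    | synthetic patients/cohorts, baseline segmenter, gain demo |
| `raclahe.cli`        | `raclahe` console script (enhance/score/benchmark/explain/phantom) |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
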