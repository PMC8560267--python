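# vesselseg

Segmentation of bright tubular ("vessel") structures in 2-D grayscale
brain-MRI slices, built for a controlled comparison of three algorithms:

1. **CNN** — a patch-based convolutional classifier of each pixel's
   17×17 neighborhood, implemented from first principles (convolution
   `h_j = f(Σ_{i∈M_j} h_i ⋆ p_ij + c_j)`, pooling
   `h_j = f(u·down(h_j) + c)`, fully connected `h = f(t·h + c)`, softmax
   cross-entropy loss) with hand-written gradients in numpy.
2. **FCN** — a fully convolutional variant with a crop layer, fixed
   bilinear ×2 upsampling, one skip connection and a two-scale multi-loss,
   segmenting images of any size; optionally refined by a conditional
   random field with Gibbs energy
   `−L(g|F) = Σ t_i(g_i) + Σ t_ij(g_i, g_j)` (unary `t_i = −log p_i`,
   Potts pairwise, ICM inference).
3. **Multimodal CNN** — the input is expanded into four channels
   (original, Gaussian, Laplacian, Gabor), each segmented by its own CNN;
   the four probability maps are merged (stacked weighted fusion by
   default) and the fused foreground score is clustered by a Gaussian
   mixture model (EM) and fuzzy C-means, whose combined soft assignment
   yields the final mask.

Segmentations are scored against ground truth with
`Dice = 2TP/(FP+2TP+FN)`, `precision = TP/(FP+TP)`, `recall = TP/(FN+TP)`,
reported as mean ± SD over images.

Clinical MRI with reference masks is rarely available, so the package
ships a seeded synthetic **phantom** generator: brain-slice-like images
with tubular structures of controlled radius and contrast, additive noise,
a smooth multiplicative bias field, and exact ground-truth masks.  Every
claim the test suite makes is made on phantoms; see `docs/methods.md` for
what that does and does not demonstrate.

## Worked example

Run the complete study — phantom generation, training of all five
networks, three-algorithm evaluation, benchmark report — from the shipped
defaults:

```bash
vesselseg runall --seed 1 --out study/
```

This writes `study/report.csv`, `study/report.json` (per-image values) and
`study/manifest.json` (config snapshot, stage seeds, artifact checksums).
A run with seed 1 prints a summary like:

```
 algorithm  n_images  dice_mean  dice_sd  precision_mean  precision_sd  recall_mean  recall_sd
       cnn         6   0.978535 0.003958        0.960895      0.006788     0.996857   0.001845
       fcn         6   0.971623 0.008483        0.945767      0.016773     0.999107   0.001018
multimodal         6   0.986168 0.003866        0.978996      0.006511     0.993466   0.002531
```

Reading the row for `multimodal`: over the 6 evaluation phantoms the final
masks overlap the ground truth with a mean Dice of 0.986; precision 0.979
means ~2% of predicted vessel pixels are false positives, and recall 0.993
means under 1% of true vessel pixels are missed.  The multimodal pipeline's
mean Dice is at least that of the single-modality CNN baseline — the
ordering the three-algorithm comparison is designed to exhibit — while both
baselines over-segment slightly (near-perfect recall, lower precision).

Individual stages are available as subcommands (`vesselseg phantom
generate`, `modality build`, `cnn train/segment`, `fcn train/segment`,
`crf refine`, `pipeline run`, `metrics evaluate`); see `--help` on each.
The same functionality is importable as a library:

```python
from vesselseg.config import PipelineConfig, phantom_benchmark

table = phantom_benchmark(seed=1, n_eval=20)   # trains + evaluates
print(table[["algorithm", "dice_mean", "dice_sd"]])
```

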