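# Methods

`vesselseg` implements and compares three segmentation algorithms for bright
tubular ("vessel") structures in 2-D grayscale brain-MRI slices: a
patch-based CNN, a fully convolutional network (FCN) with optional CRF
refinement, and a multimodal pipeline that filters the input into four
channels, segments each with its own CNN, fuses the results and produces the
final mask by GMM + fuzzy-C-means clustering.  Because clinical MRI with
ground truth is rarely shareable, the package ships a synthetic phantom
generator that provides exact reference masks; every quantitative claim the
test suite makes is made on phantoms.

## Synthetic phantoms

A phantom emulates the features of a cerebrovascular MRI slice that matter
to a segmenter: thin curvilinear bright structures over a darker tissue
background, additive acquisition noise, and a smooth multiplicative
intensity inhomogeneity (bias field).

* **Geometry.** Each vessel is a tube of constant radius around a smooth
  random-walk centerline (heading diffuses by Gaussian turns of sd 0.25 rad
  per unit step, reflected at the borders).  The mask marks every pixel
  within the radius of the polyline, computed by exact point-to-segment
  distances; the generating centerlines and radii are retained on the
  `Phantom` object so tests can re-verify the mask independently.
* **Intensity.** `image = bias × (background + vessels) + noise`, clipped to
  [0, 1].  The bias field is a broad Gaussian bump (sd 0.4–0.8 of the image
  side) scaled to a configured peak-to-peak amplitude around 1.
* **Presets.**  `easy` (64 px, 3 vessels of radius 2–4 px, intensities
  0.8 vs 0.3, noise sd 0.04, bias 0.08), `medium` (4 vessels, 1.5–3 px,
  0.7 vs 0.35, noise 0.08, bias 0.15) and `hard` (5 vessels, 1–2 px,
  0.6 vs 0.4, noise 0.12, bias 0.25).  The presets fix the vocabulary used
  by the benchmark and tests; all values are config-overridable.
* **Determinism.** A dataset is reproducible from `(config, master seed)`;
  per-image seeds derive via `numpy.random.SeedSequence([seed, index])`.

What the phantoms do **not** model: anatomy (no cortex/ventricle
structure), partial-volume effects, Rician noise statistics, coil
sensitivity profiles, or 3-D continuity of vessels across slices.  Passing
results demonstrate algorithmic correctness and the relative behavior of
the three algorithms under controlled difficulty — not clinical
performance.

## Modality filter bank

One input image becomes a four-channel stack in fixed order: original,
Gaussian-smoothed, Laplacian, Gabor.  Defaults target vessels of 2–4 px
radius: Gaussian sd 1.5 px; 5-point Laplacian stencil; Gabor frequency
0.15 cycles/px, envelope sd 3 px, four orientations combined by pixelwise
maximum of the complex magnitude.  Boundary handling is mirror-reflection
throughout, avoiding dark-border artifacts that would bias border Dice.

Each filtered channel is mapped to [0, 1] by a **fixed affine rescaling**
derived from the filter's response bounds on [0, 1] inputs, not from the
image's own extrema: the Gaussian channel is used unchanged (a unit-sum
kernel preserves the range), the Laplacian channel maps [−B, B] → [0, 1]
where B is half the stencil's L1 norm (zero response sits at 0.5), and the
Gabor magnitude is divided by the kernel's L1 bound.  Per-image min–max
normalization was rejected deliberately: it stretches the noise of a
featureless image to full contrast and makes the channel statistics depend
on image content, which destabilizes any classifier trained on the channel.
The Gabor filter subtracts the image mean first (DC correction), so
constant images produce near-zero response.

## Patch CNN

The CNN classifies the center pixel of a 17×17 patch as vessel/background.
Layers are implemented from first principles in numpy with hand-written
backward passes:

* convolution `h_j = f(Σ_{i∈M_j} h_i ⋆ p_ij + c_j)` (cross-correlation
  convention, odd kernels, valid or zero-padded same mode; an optional
  receptive table M_j restricts input maps);
* pooling `h_j = f(u_j · down(h_j) + c_j)` with mean or max reduction over
  non-overlapping windows; the multiplicative and additive deviations u, c
  are defined per map, initialized to 1 and 0, and held fixed unless
  flagged trainable (their training protocol is not prescribed anywhere, so
  the default keeps them at their neutral values);
* fully connected `h = f(t·h + c)`;
* softmax head with the mean negative log-probability of the true class as
  loss; probabilities are exp-normalized with max-subtraction.

Default architecture: conv 3×3 ×8 maps → mean-pool 2×2 → conv 3×3 ×16 →
FC 32 → FC 2, ReLU hidden activations.  This is the smallest stack that
exercises all four layer types and segments 64 px phantoms on one CPU in
seconds.  Training is plain SGD (lr 0.05, batch 64, 20 epochs, 300 patches
per image sampled class-balanced 1:1 with mirror padding at borders),
bit-reproducible under a fixed seed.  Inference slides the patch over every
pixel (stride 1 by default); a coarser stride spreads each prediction over
a small assembly window with overlap averaging, trading edge sharpness for
speed — the sharp default matters because the downstream clustering maps
soft boundaries into systematic mask dilation.

Gradient correctness is enforced by tests: analytic gradients of the loss
through a one-conv micro-model match central finite differences to 1e-4
relative error, and each layer's forward pass matches an independently
coded triple-loop oracle.

## FCN and CRF

The FCN shares the layer implementations but runs fully convolutionally
(`same` padding) on any image ≥ 8 px: conv(8) at full resolution →
mean-pool 2 → conv(16) at half resolution, then a fixed ×2 bilinear
upsampling (zero-stuffing + tent kernel, whose adjoint is exact by
symmetry), a crop layer trimming the upsampled maps back to the input
shape (pooling pads odd sizes, so upsampling can overshoot by one pixel),
a channel concatenation with the full-resolution maps (skip connection),
and a 1×1 conv head.  An auxiliary 1×1 head at half resolution contributes
a second softmax loss (labels downsampled by per-block majority, ties to
background); the total loss weights the two scales 0.7/0.3.  Feeding loss
directly to the deep layers is the standard remedy for vanishing
gradients in encoder–decoder nets.  Because vessel pixels are rare, pixel
losses weight foreground 3:1 by default.

CRF refinement treats the segmenter's probability map as unary potentials
t_i = −log p_i (probabilities clamped at 1e-10 before the log) of a Gibbs
distribution p(g|F) = exp(−L(g|F))/Z(F) whose energy adds a Potts pairwise
term t_ij = w·1[g_i ≠ g_j] over 4-neighbor edges (w = 0.5 default;
a symmetric class-compatibility matrix generalizes the Potts form).  The
partition function Z is never computed — MAP inference only compares
energies.  Inference is iterated conditional modes with checkerboard
sweeps: each half-sweep updates an independent pixel set to its locally
optimal class, so energy is non-increasing (asserted each sweep);
iteration stops on a no-change sweep or at max_iter = 20.  ICM was chosen
over mean-field because it is deterministic, monotone, and verifiable
against exhaustive enumeration on small instances; `crf_refine` can
restart from all-background / all-foreground / argmax and keep the lowest
energy.  With w = 0 the result is exactly the per-pixel argmax.

## Fusion and clustering

The four per-modality probability maps are merged per a configured rule —
unweighted mean, weighted mean, or majority vote — and renormalized.  The
pipeline default is **stacked weighted fusion**: roughly 30 % of the
training images are held out of patch training, each modality model
predicts them, and all weight vectors on a 0.05-step simplex grid are
scored by the Dice of the thresholded fused map; the best grid point wins
(ties resolve to the most diversified vector).  Uniform averaging was
measured to underperform its own best member whenever the modality
qualities differ widely — with correlated experts the combiner has to be
learned, and held-out stacking is the standard way to learn it.  The
log-odds rule w ∝ log((1−e)/e) is also provided
(`estimate_fusion_weights`) for settings without held-out data.

The fused per-pixel foreground score is then clustered twice:

* **GMM.** A two-component 1-D Gaussian mixture fitted by EM.
  Log-likelihood is non-decreasing every iteration (asserted);
  k-means++-seeded multi-start is used for generic data, but for fused
  scores the component means are anchored at 0.25/0.75 — the score is a
  calibrated probability, so the clustering refines a known bimodal
  structure rather than searching for an arbitrary one (on heavily
  imbalanced score distributions a likelihood-best restart can model
  substructure of the background instead of the vessel/background split).
  Component variances are floored at 1e-4: on a [0, 1] score scale a
  component sd below 1 % models quantization noise, and letting a
  component collapse onto a point spike would send every off-spike value
  to the other component.
* **FCM.** Fuzzy C-means with fuzzifier m = 2 minimizing Σ u²‖x−c‖²,
  alternating center/membership updates (objective non-increasing,
  asserted; memberships sum to 1; a value coinciding with a center binds
  to it; an empty cluster keeps its previous center).  Centers are
  anchored like the GMM means.

Each clustering's foreground cluster is the one with the higher
mean fused score, but only qualifies if that mean exceeds 0.5 — on a
vessel-free image the clusterings merely partition background noise and
the mask must come out empty.  The final per-pixel score is the average of
GMM foreground responsibility and FCM foreground membership, thresholded
at 0.5 with ties to background (conservative against small-vessel false
positives).

## Evaluation

For binary masks: Dice = 2TP/(FP+2TP+FN), precision = TP/(FP+TP),
recall = TP/(FN+TP).  Both-empty masks score Dice 1.0 (agreement on
emptiness), with a warning; undefined precision/recall are returned as
NaN, never silently 0.  The benchmark evaluates per image and reports
mean ± SD across images.  The terminology in the surrounding literature
sometimes calls the second metric "accuracy"; the formula implemented is
precision and it is labelled as such.

## Study runner and problem sizes

`run_all` drives the full study from one config: 14 training phantoms
(10 for patch training, 4 held out for stacking) and 6 evaluation
phantoms by default; the end-to-end benchmark used by the acceptance
checks evaluates 20 phantoms.  These sizes keep a complete study — data
generation, five network trainings, three-algorithm evaluation — around
two minutes on one CPU while leaving the comparison stable across seeds.
One global seed derives every stage seed by hashing `(seed, stage name)`
(blake2s, reduced mod 2³¹), so a run is reproducible end to end and the
report files are byte-identical across repeats; the manifest additionally
records timestamps and artifact checksums, which do differ between runs.

## Known limitations

* 2-D only; no volumetric context.
* The CNN/FCN stacks are deliberately small; they saturate on the easy
  preset and are not meant to be competitive architectures.
* The phantom noise model is Gaussian, not Rician; bias fields are single
  bumps, not multi-coil profiles.
* FCM and GMM operate on the 1-D fused score, so spatial context enters
  only through the upstream CNNs (and optionally the CRF).
* Stacked fusion weights are fitted on a handful of held-out images; with
  very small training sets they revert to uniform averaging.
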