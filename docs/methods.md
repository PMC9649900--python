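# Methods

## Problem setting

Planar bone scintigraphy records radiotracer counts in two whole-body views
(anterior and posterior, 256x1024 16-bit pixels, 2.26 mm pitch). Metastatic
lesions appear as focal high-uptake regions, but high uptake is also normal
in much of the skeleton, counts cannot be normalized to a fixed range across
patients, and expert pixel labels are scarce. `scintiseg` implements a
semi-supervised segmentation pipeline for this regime: thorax cropping and
dual-view aggregation, a three-annotator agreement protocol for the labels
that do exist, a recurrent dilated-residual/inception network, and a
combined region-energy + label-guided loss that can train on mostly
unlabeled images.

## Preprocessing

**Dual-view aggregation.** The posterior view is mirrored horizontally and
added pixel-wise to the anterior view, `out[i,j] = ant[i,j] +
post[i, W-1-j]`, so a lesion visible in either view is present in the
aggregate. Addition (not averaging) is used; counts stay integral.

**Thorax cropping** is a three-step heuristic: (1) the body box is the
bounding box of pixels above a noise threshold (default 0 counts) plus an
optional margin; (2) the upper body is the top fraction (default 45%) of
the body box; (3) the thoracic window starts below a head/shoulder line at
a fixed fraction (default 12%) of body height, is width-centered on the
body, and is zero-padded to exactly 256x256 (configurable `out_size`).
Padding, not resampling, is used when the window is narrower than the
output: it preserves counts exactly and keeps the crop invertible. All
fractions are configuration, since the original cropping procedure this
step stands in for is not published in reproducible detail.

**Normalisation** is deliberately separate from I/O. The default
`per-image max` strategy divides by the image maximum (all-zero images map
to zeros), which is invariant under integer rescaling of the counts;
fixed-range and percentile clipping are selectable alternatives. The
strategy is an explicit argument rather than a constant because no fixed
normalisation is defensible across patients.

## Annotation protocol

Each lesion is outlined by three annotators as a closed polygon. Pixel
membership uses pixel centers (integer coordinates, origin top-left), with
boundary pixels included. The pairwise disagreement of two outlines is
`dA = 1 - IoU` of the rasterized masks; a lesion's triplet is accepted when
the largest of its three pairwise `dA` values is at most `t_dA = 0.05`, and
one of the three outlines is then chosen uniformly at random (seeded) as
ground truth. Rasterized (pixel) IoU is used rather than analytic polygon
IoU because every downstream loss and metric is pixel-based; the analytic
value serves as a cross-check oracle in tests. Agreement is assessed per
lesion, with lesions matched across annotators by identifier; a lesion
annotated by only some annotators is a hard error rather than a silent
skip.

## Network

The feature extractor is an encoder-decoder:

* **Dilated residual blocks** (encoder): two 3x3 dilated convolutions
  (dilation 2, "same" padding), each followed by batch normalisation and
  PReLU, summed with a 1x1 convolution skip path. Dilated convolution
  arithmetic: effective kernel `n = k + (k-1)(d-1)`, output size
  `o = floor((i + 2p - n)/s) + 1`.
* **Inception bottleneck**: five parallel branches (factorized 1x3/3x1,
  factorized 1x7/7x1, 1x1, 5x5, and 1x1 followed by 2x2 max pooling), each
  ending at stride 2, depth-concatenated; it halves the grid resolution.
* **Decoder**: per stage, a 1x1 channel-reducing convolution, bilinear 2x
  upsampling, and a 3x3 convolution with BN + PReLU, restoring full
  resolution.

**Recurrence.** The extractor output, concatenated with the raw input
image as one extra channel (a long skip from the network input, so the
recurrence sees count intensity directly alongside the extracted
features), drives a recurrent state
`x_t = PReLU(W_F * u + W_R * x_{t-1} + b)` with `x_0 = 0`, 3x3
convolutions for both the feedforward (`W_F`) and recurrent (`W_R`) paths,
and `t = 3` steps by default. The input skip matters for optimization:
without it, early training can push the whole membership map coherently
toward one phase before the deep features learn to separate lesion from
background, and the run stalls in a saturated configuration. Because the network input is the same image
at every step, the feedforward convolution is computed once and reused
across the unroll; this is algebraically identical to re-running the
extractor per step with shared weights. Weights are shared across steps by
default (unrolling adds no parameters); an unshared mode with per-step
`(W_F, W_R, b)` is available. A 1x1 head maps the final state to per-pixel
logits; the lesion membership map is the logistic of the logits,
binarized at 0.5.

Channel widths are configuration. The full-scale profile is
`[16, 32, 64, 128]` at 256x256; the desk-scale profile used by the phantom
experiments is `[3, 6, 12]` at 64x64 (about 2,000 parameters), chosen so
the full study design runs in minutes on one CPU core while remaining
expressive enough to solve the phantom task.

## Loss

The combined loss is `l = l_U + alpha * l_S` with `alpha = 0.4`;
`l_S` is added only for labeled samples.

**Unsupervised region energy** (applied to every sample):

    l_U = v * sum(m) + sum(m * (g - c1)^2) + sum((1 - m) * (g - c2)^2)

with `g` the normalized image, `m` in [0,1] the membership map,
`c1`/`c2` the soft means inside/outside, and `v = 0.004` the area weight.
This is the two-phase piecewise-constant region energy with the crisp set
indicators relaxed to soft weights `m` and `1 - m`, so it is
differentiable end to end; a hard 0/1 membership recovers the crisp energy
exactly, which the oracle tests exploit. Empty regions have mean 0 by
convention (implemented with a 1e-30 denominator guard, far below one
pixel of soft mass). Gradients flow through `c1`/`c2` as well as the
residuals.

**Supervised term** (labeled samples):

    l_S = TV(m) + sum((1 - 2*mu) * m)

where `mu` is the per-pixel binary label (background 0) and TV is the
anisotropic total variation with forward differences and replicate
boundary (border differences vanish). The region term is linear in `m`:
`-m` on lesion pixels, `+m` on background, so it rewards confident
membership exactly where the annotator drew and penalizes it elsewhere.

**Scaling.** The public loss functions return sums, matching the worked
values (`l_U = 0.064` for a 16-pixel region at `v = 0.004`). The training
loop divides by the pixel count per image (and the supervised term by the
labeled-subset size), which rescales the gradient without changing the
relative weighting of any term; this keeps a single learning rate usable
across image sizes.

## Training and evaluation protocol

* Patient-grouped split: whole patients (including every augmented copy of
  a source image) are assigned to one side, with the train share nearest
  70%. The labeled subset is drawn uniformly (seeded) from train samples
  that have consensus masks.
* Optimizer: Adam, learning rate 5e-4, beta1 = 0.9 (the configured
  momentum), beta2 = 0.999, weight decay 1e-4 added to the gradient;
  defaults follow the published training configuration. Batches mix
  labeled and unlabeled samples, with the loss branch decided per sample.
* Evaluation: pixel-wise DSC = 2TP/(FP+2TP+FN), CPA = TP/(TP+FP) and
  Recall = TP/(TP+FN), lesion as the positive class; per image, then
  averaged. Two empty masks give DSC = 1; CPA/Recall with empty
  denominators are reported as missing and excluded from averages. The
  repeated-runs protocol evaluates 10 times and averages; the model is
  deterministic at inference, so the runs coincide (sd 0) but are still
  executed and logged.
* Polarity: the two-phase region energy is invariant under swapping the
  inside/outside labels, so a run trained with few or no labels can
  converge with inverted membership. Lesions are by definition the
  high-uptake class, so at inference the membership map is flipped when
  the predicted inside is darker on average than the outside (the
  standard bright-phase convention; a no-op whenever training already
  anchored the polarity).
* Boundary delineation: 8-connected components of the binary mask with at
  least `min_area = 4` pixels each yield one closed sub-pixel contour
  (marching squares at the 0.5 level), exported as polygon annotations.

## Synthetic phantoms

Clinical scans are not redistributable, so all experiments run on
generated phantoms: an elliptical torso at 50 mean counts with a bright
spinal band (2.6x background) and rib stripes (1.9x), 1-5 non-overlapping
elliptical lesions with semi-axes 4-8 px (at 64x64; scaled with image
size) and intensities 2-8x background, each placed in the anterior view,
the posterior view (mirrored position), or both; the posterior view is the
mirrored template attenuated to 70% with independent noise. Counts are
Poisson-sampled around the noiseless template. Ground truth is the union
of lesion supports in the aggregated frame. Triple annotations are
ellipse outlines with Gaussian radial vertex jitter plus a small rigid
shift; the default jitter (0.045 px scale) is calibrated against the
agreement gate so that mean pairwise `dA` is ~0.02 and well over 90% of
triplets pass the 5% threshold — on few-pixel lesions rasterized IoU is
quantized, so hitting a 90% pass rate requires the mean to sit below the
gate with margin.

What the phantoms emulate: Poisson count statistics, dual views with
attenuation, bright non-lesion anatomy overlapping the lesion intensity
range (which is what makes purely unsupervised region segmentation
insufficient and labels informative), lesion variability in size, shape,
intensity and view visibility, and imperfect manual annotation. What they
do not: anatomical realism, scatter and collimator physics, lesion
texture, or inter-patient anatomy variation. Passing phantom experiments
therefore demonstrates that the pipeline's machinery behaves as designed
under the assumed statistical structure, not clinical-grade accuracy.

## Phantom study design (desk scale)

* **Label-fraction sweep**: 200 train / 60 test images at 64x64, 20
  epochs, label fractions {0, 0.1, 0.37, 0.7}, five training seeds. The
  expected pattern — test DSC non-decreasing in the label fraction within
  one standard deviation, with the 37% run clearly above the fully
  unsupervised run — mirrors the design of the original labeled-sample
  experiments. The unsupervised run plateaus around DSC 0.6 because it
  cannot distinguish bright normal skeleton from lesions; labels close
  that gap.
* **Ablation**: plain convolutional baseline (no dilation, no inception,
  no residual skip) vs the full extractor, 120/40 images, 12 epochs, three
  seeds, shared splits.
* **Chan–Vese recovery**: direct Adam descent on the membership logits of
  a noiseless two-level 64x64 image under the unsupervised energy reaches
  DSC >= 0.99 within 500 iterations. The logits are initialized
  proportional to the centered image (4 * (g - mean(g))): with a constant
  initialization the two-phase energy starts at a symmetric stationary
  configuration (c1 = c2) where the only gradient is the area term, so
  intensity-proportional initialization is used to break the symmetry.

## Numerical choices

* The network, GAN and training run in float32 on a small in-package
  reverse-mode autodiff engine (im2col convolutions with stride, dilation
  and zero padding; fused batch-norm and PReLU primitives; bilinear
  upsampling as a separable linear operator). The numpy loss paths used by
  the oracle tests are float64. Everything is seeded and single-threaded
  deterministic; fixed seeds reproduce training bit-for-bit on CPU.
* Stride-1 convolution input gradients are computed as a convolution with
  the flipped, channel-transposed kernel (full padding); strided
  convolutions use an index scatter.
* BN: momentum 0.1, eps 1e-5, running statistics for evaluation. PReLU
  slopes initialize at 0.25. He initialisation for convolution weights;
  recurrent kernels start at half scale.
* Sigmoid inputs are clamped to +/-60 before exponentiation.
* DCGAN: the generator uses nearest/bilinear upsample + 3x3 convolution
  blocks rather than transposed convolutions (avoids checkerboard
  artifacts; the original architecture is not specified at this level of
  detail), the discriminator three stride-2 blocks; k = 3 discriminator
  steps per generator step; the discriminator maximizes the minimax value
  E[log D(x)] + E[log(1 - D(G(z)))] while the generator minimizes via the
  standard non-saturating surrogate. GAN samples carry no masks and only
  ever enter the unsupervised loss branch.

## Known limitations

* The desk-scale model is tiny by design; headline clinical scores from
  full-scale training are out of scope, and no claim is made that phantom
  DSC values transfer to patient data.
* The cropping heuristic approximates a three-step procedure whose
  original implementation is unpublished; on atypical acquisitions the
  fractions may need retuning.
* The geometric augmentation recipe (2 flips x 5 rotations x 2
  translations, 19 variants + original per source) reproduces the ~20x
  dataset enlargement only in scale; the original transform multiplicities
  are not published.
* Per-lesion agreement requires consistent lesion identifiers across
  annotators; no automatic spatial correspondence is attempted.
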