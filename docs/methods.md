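# Methods

## Problem and model

The package translates single-channel T2-weighted (TSE-SSH) MR transverse
slices into CT-valued slices in Hounsfield Units, so that electron-density
information can be obtained without a CT acquisition.  The translation
model is a conditional GAN in the image-to-image tradition: the input MR
slice itself is the conditioning signal, no explicit noise vector is used
(noise is treated as embedded in the input and modelled by dropout), and
the generator objective couples the adversarial term with a strong L1
reconstruction penalty,

    L_total = L_cGAN(D, G) + λ · L1(G),        λ = 100 by default.

The generator is deliberately *shallow*: a U-Net with encoder/decoder
depth 2.  The design premise is that for limited training data a smaller
parameter budget mitigates vanishing gradients and overfitting while the
skip concatenations preserve the fine detail a voxelwise intensity mapping
needs.  A conventional depth-3 U-Net generator is included as the
benchmark; both share the same three-block conditional patch
discriminator.

## Reference architectures and the parameter-count anchors

The published description of these models fixes their structure in words
(conv / batch-norm / ReLU blocks, 2×2 max pooling, up-convolutions, skip
concatenations, three discriminator blocks, sigmoid output) and pins two
bit-exact anchors: 3,163,142 trainable parameters for the shallow model
and 4,868,614 for the benchmark, a difference of 1,705,472 (35%).  The
stage-wise feature counts are only shown in a figure, so this package
treats the two totals as checksums: the reference specs were obtained by a
constrained search over feature counts and the structural freedoms the
text leaves open (bias usage, batch-norm placement, kernel sizes), and the
build is accepted only because `count_trainable_parameters` on the real
networks reproduces both totals and their difference exactly.

A parity argument shows the totals (both ≡ 6 mod 8) are unreachable if
every feature count is a multiple of 8 under a conv+bias+batch-norm
inventory, so non-power-of-two widths are necessarily involved somewhere.
The frozen reference configuration is:

* **Shallow generator** (depth 2): stage features (64, 128, 256) — the
  classic U-Net progression — two 3×3 conv+BN+ReLU blocks per stage,
  biases everywhere, 2×2 stride-2 up-convolutions, 1×1 final convolution;
  1,864,257 parameters.
* **Discriminator**: blocks (84, 248, 496), 3×3 stride-2 convolutions,
  batch norm on blocks 2 and 3 (none on the first block, following
  image-translation discriminator convention), final 1×1 convolution and
  sigmoid; 1,298,885 parameters.
* **Benchmark generator** (depth 3): same block family with stage features
  (44, 128, 204, 216); 3,569,729 parameters.

The checksum solution is not unique; this one was selected for having the
textbook shallow-generator widths.  Everything is config-exposed, so users
can instantiate any other width assignment.

## Numerical implementation

All layers, their backward passes, and Adam are implemented in numpy
(`sucgan.nn`): im2col convolutions, exact non-overlapping transposed
convolutions (kernel = stride = 2), batch normalization with minibatch
statistics, first-index tie-breaking max pooling, inverted dropout.
Analytic gradients are validated against central differences in the test
suite.  Two numerical conventions matter:

* **Batch norm with minibatch 1.** The protocol trains with minibatch 1,
  so "batch" statistics are per-slice spatial statistics, and the same
  statistics are used at prediction time.  Training and prediction
  therefore run the identical computation.  Running averages are tracked
  but are not trainable and never used for inference.  A corollary: score
  maps collapsed to 1×1 spatial size make batch norm annihilate its input,
  so discriminator inputs should stay ≥ 16×16 (three stride-2 blocks leave
  2×2 patches).
* **Score clamping.** Discriminator outputs are clamped to
  [1e−7, 1−1e−7] before logarithms; the clamp's gradient is zero where
  active.  The generator uses the non-saturating −log D(G(y)) surrogate,
  which has the same fixed points as the min-max form but does not vanish
  when the discriminator wins early.

## Intensity handling

MR volumes are min-max normalized per volume (the simplest reading of
"normalized to [0, 1]"); the scale is recorded for inversion.  CT training
targets are mapped to [0, 1] with a *fixed* global HU window, default
[−1024, 3071], and predictions are mapped back with the same window — the
held-out subject's own CT range must never leak into its prediction.
Whole-volume metrics exclude exterior air with a body mask built by
thresholding at −400 HU, morphological closing, largest connected
component, and per-slice hole filling, so interior air (bowel/rectal
lumen) stays inside the mask.

## Training protocol

Per minibatch (default size 1): one discriminator Adam step on the binary
cross-entropy of its real and fake score maps, then one generator Adam
step on the non-saturating adversarial term plus λ·L1.  The slice pool is
every transverse slice of every training case plus a left/right-flipped
copy (exact doubling); it is reshuffled every epoch from a single seeded
generator, which makes whole training runs bit-reproducible.  Defaults
follow the reference protocol: λ = 100, 200 epochs, He initialization
(variance 2/fan-in, fan-in = kernel area × input channels), Adam with
moment decays (0.5, 0.999).  The learning rate is unreported in the source
protocol; the package default is 2e−4 (the image-translation lineage
value), and desk-scale tests use 2e−3 to reach the converged regime within
a test budget — both are ordinary `TrainConfig` fields.

## The phantom cohort

Clinical data behind the method are private, so the package generates
paired pseudo-MR/pseudo-CT pelvis phantoms: an elliptical torso with a
subcutaneous fat ring, two circular femurs with a cortical intensity
gradient, an ellipsoidal fluid-filled bladder, a tubular anorectum wall
around an air lumen, and a tumor blob between bladder and anorectum.
Geometry parameters are drawn per subject from seeded uniform ranges; the
default cohort mirrors the study's shape exactly (11 subjects, 144×144
grid, 3.2×3.2×5 mm voxels, 50 slices for subjects 1, 2, 3, 5 and 44
otherwise, 508 slices in total), which makes the leave-one-out split sizes
(458/50 and 464/44) reproducible arithmetic.

Both modalities derive from one latent per-voxel texture field t ∈ [0, 1]:
MR = mr_lo + t·(mr_hi − mr_lo) and HU = hu_lo + t·(hu_hi − hu_lo) per
tissue, plus independent Gaussian noise per modality.  MR contrast is
T2-like (fluid > tumor > soft tissue > fat > bone ≈ air).  With noise
disabled the CT is therefore an exact, monotone, per-tissue function of
the MR (`true_forward_map`), giving the package a ground truth that
clinical data cannot provide: a trained generator can be tested for
*mapping recovery*, not just loss decrease.

What the phantom does **not** emulate: anatomical shape realism, partial
volume effects, MR bias fields or distortion, registration error between
the modalities, intensity inhomogeneity across slices, and inter-tissue
HU overlap beyond the configured ranges.  Passing the phantom tests
therefore demonstrates that the implementation optimizes its objective and
recovers a recoverable cross-modality mapping under clean conditions; it
does not certify clinical accuracy, and the published patient-cohort
metric values are out of reach of any simulation.

## Desk-scale test conditions

The stochastic training properties are exercised at desk scale: 64×64
noise-free phantoms, 7 subjects × 8 slices (one held out), narrow networks
(generator stages 16/32/64, discriminator blocks 8/16/32, dropout 0),
16 epochs at learning rate 2e−3, three seeds.  Under these conditions the
epoch-mean L1 decreases monotonically from first to last epoch and the
held-out subject's air-masked MAPE (31–70 HU across seeds) beats the
constant prediction at the training cohort's mean body HU (~73 HU).  Two
empirical observations from calibrating these conditions: generalization
to a held-out subject improves far more with additional training subjects
than with additional epochs (fully convolutional networks still absorb
subject geometry through border effects when the cohort is tiny), and
held-out error under adversarial training is not monotone in epochs, so
"train longer" is not a substitute for "train broader".

## Known limitations

* 2-D slice-wise translation only; no 3-D context.
* Global (non-windowed) SSIM as specified by the evaluation protocol —
  values are not comparable to windowed SSIM implementations.
* PSNR's MAX defaults to the masked measured-CT maximum and SSIM's
  stabilizers to (0.01·L)², (0.03·L)² with L the CT window width; both are
  config-exposed and reported alongside results.
* The numpy training loop is single-threaded BLAS-bound; it is meant for
  method study and testing, not for clinical-scale 200-epoch runs on
  144×144 cohorts.
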