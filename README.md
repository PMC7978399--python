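# sucgan — synthetic CT from a single T2-weighted MR channel

`sucgan` implements MR-to-CT image translation for the female pelvis with a
conditional generative adversarial network whose generator is a *shallow*
U-Net (encoder/decoder depth 2, "sU-Net").  The intended users are medical
imaging researchers who need a CT-valued volume — electron-density
information in Hounsfield Units — from the T2-weighted, turbo-spin-echo
single-shot MR sequence that is already acquired for diagnosis, e.g. for
PET/MR attenuation correction or MR-only radiotherapy planning, without an
extra CT scan and its registration burden.

## The model

A generator `G` maps a single-channel 2-D transverse MR slice `y` to a
CT-like slice `G(y)`; a conditional discriminator `D(x|y)` scores how
plausible a candidate CT slice `x` is given the MR slice.  Training plays
the usual min-max game

```
L_cGAN(D, G) = E[log D(x|y)] + E[log(1 − D(G(y)|y))]
```

regularized by the mean absolute reconstruction error

```
L1(G) = E[‖x − G(y)‖₁],      L_total = L_cGAN(D, G) + λ·L1(G),  λ = 100.
```

The generator is a U-Net of depth 2: two encoder stages
(conv 3×3 → batch norm → ReLU, twice per stage, then 2×2 max pooling), a
bottleneck, and two decoder stages (2×2 up-convolution, concatenation with
the matching encoder features, conv blocks), with stage features
(64, 128, 256).  The discriminator has three stride-2 conv/batch-norm/ReLU
blocks (84, 248, 496 features), a final 1×1 convolution and a sigmoid,
producing a patch score map in [0, 1].  The shallow model totals
**3,163,142** trainable parameters; the conventional depth-3 benchmark
generator with the same discriminator totals **4,868,614** — a reduction of
1,705,472 parameters (35%).

Training follows the reference protocol: He initialization, Adam,
minibatch 1, left/right flip augmentation, 200 epochs, leave-one-out
validation across subjects.  Evaluation reports MAPE (mean absolute error
in HU — the name is the field's convention for this task), RMSE, PSNR and a
global SSIM statistic, whole-body (air-masked) and per contour (GTV, both
femurs, bladder, anorectum), plus HU histograms.

Because the clinical cohort is private, the package ships a procedural
paired pelvis phantom (`sucgan.phantoms`): an elliptical torso with femurs,
bladder, anorectum and tumor whose pseudo-MR and pseudo-CT derive from a
shared latent texture through a known per-tissue monotone map — so the
mapping the network must learn is exactly recoverable and testable.

All networks, backward passes and the Adam optimizer are implemented in
numpy (`sucgan.nn`); gradients are verified against numerical
differentiation in the test suite.

## Worked example

```python
from sucgan import (PhantomConfig, SynthCTModel, TrainConfig,
                    GeneratorSpec, DiscriminatorSpec, generate_cohort)

cohort = generate_cohort(PhantomConfig(
    n_subjects=7, grid=(64, 64), slice_count_choices=(8,),
    noise_sd={"MR": 0.0, "CT": 0.0}, seed=7))

model = SynthCTModel(
    cohort[1:],                          # train on six subjects
    generator_spec=GeneratorSpec(depth=2, stage_features=(16, 32, 64),
                                 dropout_rate=0.0),
    discriminator_spec=DiscriminatorSpec(block_features=(8, 16, 32),
                                         kernel_size=3),
    config=TrainConfig(epochs=16, seed=0, learning_rate=2e-3))
results = model.fit()
print(results.summary())

reports = results.evaluate(cohort[0])    # held-out subject
for r in reports:
    print(f"{r.region:12s} MAPE {r.mape:7.1f} HU   SSIM {r.ssim:.3f}")
```

Output:

```
Synthetic-CT translation model (conditional GAN)
================================================
generator depth:        2
stage features:         (16, 32, 64)
trainable parameters:   123,498
training cases:         6
epochs:                 16
lambda (L1 weight):     100
generator steps:        1536

first-epoch mean L1:    0.04764
final-epoch mean L1:    0.00471
final-epoch mean D loss:1.36512
final-epoch mean G loss:1.24358

whole_body   MAPE    31.2 HU   SSIM 0.965
GTV          MAPE    15.0 HU   SSIM 0.972
femur_R      MAPE    91.5 HU   SSIM 0.949
femur_L      MAPE   208.5 HU   SSIM 0.707
bladder      MAPE    24.9 HU   SSIM 0.834
anorectum    MAPE    24.6 HU   SSIM 0.941
```

The epoch-mean L1 falls by an order of magnitude over training, and the
held-out whole-body MAPE of ~31 HU beats the constant-prediction baseline
(~73 HU for this cohort): the network has recovered the phantom's MR→HU
mapping rather than memorized the training subjects.  Errors concentrate
in bone, whose 1100-HU cortical range is the hardest regime — the same
qualitative pattern the method shows on clinical data.

A command-line workflow is also available:

```bash
sucgan simulate --out cohort/ --seed 1
sucgan train --data cohort/cohort_manifest.csv --out model.npz --seed 1
sucgan predict --ckpt model.npz --mr cohort/S01_mr.nii.gz --out S01_sct.nii.gz
sucgan evaluate --ct cohort/S01_ct.nii.gz --sct S01_sct.nii.gz --out eval/
sucgan loo --data cohort/cohort_manifest.csv --out loo/ --seed 1
```

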