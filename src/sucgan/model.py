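"""Model/Results front end over the translation pipeline.

``SynthCTModel`` bundles a cohort of paired cases with the network
architecture and training protocol; ``fit`` runs the adversarial training
and returns a ``SynthCTResults`` carrying the trained networks, the loss
history, and evaluation helpers, in the spirit of the model/results split
used by statistical modelling packages.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence

import pandas as pd

from .evaluation import MetricsReport, SSIMParams, contour_metrics, summarize_cohort
from .experiment import ExperimentManifest, loo_splits, run_loo_experiment
from .nn import (DiscriminatorSpec, GeneratorSpec, PatchDiscriminator,
                 UNetGenerator, count_trainable_parameters, he_initialize,
                 reference_discriminator_spec, reference_sunet_spec)
from .training import TrainConfig, TrainingHistory, predict_volume, train
from .volumes import PairedCase, VoxelVolume

__all__ = ["SynthCTModel", "SynthCTResults"]


class SynthCTModel:
    """An MR -> synthetic-CT translation model bound to a training cohort.

    Parameters
    ----------
    cases : sequence of PairedCase
        Co-registered MR/CT pairs used for training.
    generator_spec, discriminator_spec : optional
        Network architectures; the reference shallow U-Net generator and
        three-block conditional discriminator are used when omitted.
    config : TrainConfig, optional
        Training protocol; study defaults (lambda=100, minibatch 1, Adam,
        flip augmentation) when omitted.
    """

    def __init__(self, cases: Sequence[PairedCase],
                 generator_spec: Optional[GeneratorSpec] = None,
                 discriminator_spec: Optional[DiscriminatorSpec] = None,
                 config: Optional[TrainConfig] = None):
        if not cases:
            raise ValueError("the model needs at least one paired case")
        self.cases = list(cases)
        self.generator_spec = generator_spec or reference_sunet_spec()
        self.discriminator_spec = discriminator_spec or reference_discriminator_spec()
        self.config = config or TrainConfig()

    @property
    def n_parameters(self) -> int:
        """Trainable parameters of generator plus discriminator."""
        return count_trainable_parameters(
            UNetGenerator(self.generator_spec),
            PatchDiscriminator(self.discriminator_spec))

    def fit(self, seed: Optional[int] = None) -> "SynthCTResults":
        """He-initialize fresh networks and run the adversarial training."""
        cfg = self.config if seed is None else dataclasses.replace(
            self.config, seed=int(seed))
        gen = he_initialize(UNetGenerator(self.generator_spec), seed=cfg.seed)
        disc = he_initialize(PatchDiscriminator(self.discriminator_spec),
                             seed=cfg.seed + 10_000)
        gen, disc, history = train(gen, disc, self.cases, cfg)
        return SynthCTResults(self, gen, disc, history, cfg)

    def fit_loo(self, out_dir, **kwargs) -> ExperimentManifest:
        """Run the full leave-one-out experiment over the cohort."""
        return run_loo_experiment(self.cases, self.config, out_dir,
                                  generator_spec=self.generator_spec,
                                  discriminator_spec=self.discriminator_spec,
                                  **kwargs)

    def splits(self):
        return loo_splits(self.cases)


class SynthCTResults:
    """A fitted translation model: trained networks plus diagnostics."""

    def __init__(self, model: SynthCTModel, generator: UNetGenerator,
                 discriminator: PatchDiscriminator, history: TrainingHistory,
                 config: TrainConfig):
        self.model = model
        self.generator = generator
        self.discriminator = discriminator
        self.history = history
        self.config = config

    def predict(self, mr: VoxelVolume, dropout_seed: int = 0) -> VoxelVolume:
        """Synthesize a CT (HU) volume from an MR volume."""
        return predict_volume(self.generator, mr, self.config.ct_scale,
                              dropout_seed=dropout_seed)

    def evaluate(self, case: PairedCase, ssim_params: SSIMParams = SSIMParams(),
                 dropout_seed: int = 0) -> List[MetricsReport]:
        """Predict a case's synthetic CT and score it against the measured CT."""
        sct = self.predict(case.mr, dropout_seed=dropout_seed)
        return contour_metrics(case, sct, ssim_params)

    def evaluate_cohort(self, cases: Sequence[PairedCase],
                        ssim_params: SSIMParams = SSIMParams()) -> pd.DataFrame:
        reports: List[MetricsReport] = []
        for case in cases:
            reports.extend(self.evaluate(case, ssim_params))
        return summarize_cohort(reports)

    def summary(self) -> str:
        """Human-readable fit summary."""
        df = self.history.to_dataframe()
        first = df[df.epoch == df.epoch.min()]
        last = df[df.epoch == df.epoch.max()]
        lines = [
            "Synthetic-CT translation model (conditional GAN)",
            "=" * 48,
            f"generator depth:        {self.model.generator_spec.depth}",
            f"stage features:         {self.model.generator_spec.stage_features}",
            f"trainable parameters:   {self.model.n_parameters:,}",
            f"training cases:         {len(self.model.cases)}",
            f"epochs:                 {self.config.epochs}",
            f"lambda (L1 weight):     {self.config.lambda_l1:g}",
            f"generator steps:        {len(self.history)}",
            "",
            f"first-epoch mean L1:    {first.l1.mean():.5f}",
            f"final-epoch mean L1:    {last.l1.mean():.5f}",
            f"final-epoch mean D loss:{last.d_loss.mean():.5f}",
            f"final-epoch mean G loss:{last.g_total.mean():.5f}",
        ]
        return "\n".join(lines)
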