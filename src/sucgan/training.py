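"""Alternating generator/discriminator training and volume prediction.

The training protocol mirrors the study design: minibatch size 1, Adam,
``lambda = 100`` on the L1 term, 200 epochs by default, left/right flip
augmentation of the slice pool, and one discriminator step followed by one
generator step per minibatch.

Intensity handling: MR inputs are min-max normalized per volume; CT targets
are mapped to [0, 1] with a fixed global HU window (default [-1024, 3071])
so that prediction-time denormalization never depends on the held-out
subject's CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import losses
from .nn import Adam, PatchDiscriminator, UNetGenerator
from .volumes import (IntensityScale, PairedCase, VoxelVolume, denormalize,
                      normalize_to_unit)

__all__ = [
    "DEFAULT_CT_SCALE",
    "TrainConfig",
    "TrainingHistory",
    "build_slice_pool",
    "train",
    "predict_volume",
]

#: Fixed HU window used to put CT targets on the [0, 1] network scale.
DEFAULT_CT_SCALE = IntensityScale(-1024.0, 3071.0)


@dataclass
class TrainConfig:
    """Hyperparameters of the adversarial training loop."""

    lambda_l1: float = 100.0
    epochs: int = 200
    minibatch: int = 1
    learning_rate: float = 2e-4
    adam_betas: Tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    augment_flip: bool = True
    device: str = "cpu"
    ct_scale: IntensityScale = field(default_factory=lambda: DEFAULT_CT_SCALE)

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainingHistory:
    """One record per generator step."""

    epoch: List[int] = field(default_factory=list)
    d_loss: List[float] = field(default_factory=list)
    g_adv: List[float] = field(default_factory=list)
    l1: List[float] = field(default_factory=list)
    g_total: List[float] = field(default_factory=list)

    def append(self, epoch: int, d_loss: float, g_adv: float, l1: float,
               g_total: float) -> None:
        for v in (d_loss, g_adv, l1, g_total):
            if not np.isfinite(v):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: d={d_loss}, adv={g_adv}, "
                    f"l1={l1}, total={g_total}")
        self.epoch.append(epoch)
        self.d_loss.append(d_loss)
        self.g_adv.append(g_adv)
        self.l1.append(l1)
        self.g_total.append(g_total)

    def __len__(self) -> int:
        return len(self.epoch)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epoch, "d_loss": self.d_loss, "g_adv": self.g_adv,
            "l1": self.l1, "g_total": self.g_total,
        })

    def epoch_mean(self, column: str) -> pd.Series:
        df = self.to_dataframe()
        return df.groupby("epoch")[column].mean()


def _normalize_case(case: PairedCase, ct_scale: IntensityScale):
    mr_norm, _ = normalize_to_unit(case.mr)
    ct_norm = np.clip((case.ct.data - ct_scale.lo) / ct_scale.width, 0.0, 1.0)
    return mr_norm.data, ct_norm


def build_slice_pool(cases: Sequence[PairedCase], augment_flip: bool,
                     ct_scale: IntensityScale = DEFAULT_CT_SCALE):
    """Normalized 2-D training pairs from all transverse slices of all cases.

    When ``augment_flip`` is set, a left/right-mirrored copy of every slice
    is appended, exactly doubling the pool.
    """
    pool: List[Tuple[np.ndarray, np.ndarray]] = []
    for case in cases:
        mr, ct = _normalize_case(case, ct_scale)
        for k in range(case.n_slices):
            pool.append((mr[:, :, k], ct[:, :, k]))
            if augment_flip:
                pool.append((mr[::-1, :, k].copy(), ct[::-1, :, k].copy()))
    if not pool:
        raise ValueError("empty slice pool")
    return pool


def train(gen: UNetGenerator, disc: PatchDiscriminator,
          cases: Sequence[PairedCase], config: TrainConfig
          ) -> Tuple[UNetGenerator, PatchDiscriminator, TrainingHistory]:
    """Alternating adversarial training over the cohort slice pool.

    For every minibatch the discriminator takes one Adam step on the binary
    cross-entropy of its real and fake score maps, then the generator takes
    one Adam step on the non-saturating adversarial term plus
    ``lambda * L1``.  Deterministic for a fixed config seed.
    """
    pool = build_slice_pool(cases, config.augment_flip, config.ct_scale)
    rng = np.random.default_rng(config.seed)
    opt_g = Adam(gen.params(), lr=config.learning_rate, betas=config.adam_betas)
    opt_d = Adam(disc.params(), lr=config.learning_rate, betas=config.adam_betas)
    history = TrainingHistory()

    for epoch in range(config.epochs):
        order = rng.permutation(len(pool))
        for start in range(0, len(order), config.minibatch):
            idx = order[start:start + config.minibatch]
            mr = np.stack([pool[i][0] for i in idx])[:, None]
            ct = np.stack([pool[i][1] for i in idx])[:, None]

            gx = gen.forward(mr, train=True, rng=rng)

            # --- discriminator step ------------------------------------
            opt_d.zero_grad()
            d_real = disc.forward(np.concatenate([mr, ct], axis=1), train=True, rng=rng)
            g_real, _ = losses.grad_discriminator_loss(d_real, d_real)
            disc.backward(g_real)
            d_fake = disc.forward(np.concatenate([mr, gx], axis=1), train=True, rng=rng)
            _, g_fake = losses.grad_discriminator_loss(d_fake, d_fake)
            disc.backward(g_fake)
            d_loss = losses.discriminator_loss(d_real, d_fake)
            opt_d.step()

            # --- generator step ----------------------------------------
            opt_g.zero_grad()
            opt_d.zero_grad()  # D gradients from this pass are discarded
            d_fake2 = disc.forward(np.concatenate([mr, gx], axis=1), train=True, rng=rng)
            adv = losses.generator_adversarial_loss(d_fake2)
            l1 = losses.l1_term(ct, gx)
            grad_in = disc.backward(losses.grad_generator_adversarial_loss(d_fake2))
            grad_gx = grad_in[:, 1:2] + config.lambda_l1 * losses.grad_l1_term(ct, gx)
            gen.backward(grad_gx)
            opt_g.step()
            opt_d.zero_grad()

            history.append(epoch, d_loss, adv, l1,
                           losses.total_generator_loss(adv, l1, config.lambda_l1))
    return gen, disc, history


def predict_volume(gen: UNetGenerator, mr: VoxelVolume,
                   ct_scale: IntensityScale = DEFAULT_CT_SCALE,
                   dropout_seed: int = 0) -> VoxelVolume:
    """Synthesize a CT volume from an MR volume, slice by slice.

    The MR volume is min-max normalized, each transverse slice is pushed
    through the generator, and the stacked output is mapped back to HU with
    the (training-cohort) CT scale.  Deterministic for a fixed trained
    generator and ``dropout_seed``.
    """
    rng = np.random.default_rng(dropout_seed)
    mr_norm, _ = normalize_to_unit(mr)
    out = np.empty_like(mr_norm.data)
    for k in range(mr.shape[2]):
        x = mr_norm.data[:, :, k][None, None]
        out[:, :, k] = gen.forward(x, train=False, rng=rng)[0, 0]
    sct_norm = VoxelVolume(np.clip(out, 0.0, 1.0), spacing_mm=mr.spacing_mm,
                           modality="SCT", intensity_domain="normalized")
    return denormalize(sct_norm, ct_scale, domain="HU")
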