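"""U-Net generators and the conditional patch discriminator.

The generator is an encoder/decoder U-Net whose depth is configurable: the
shallow variant uses depth 2 (two pooling steps), the conventional benchmark
depth 3.  Both are fully convolutional, so any input whose in-plane
dimensions are divisible by ``2**depth`` is accepted and mapped to an output
of the same size.

The discriminator is conditional: it scores the (MR, CT-candidate) pair as a
2-channel input and emits a patch score map squashed to [0, 1] by a sigmoid.

Architecture hyperparameters live in declarative spec dataclasses;
:func:`reference_sunet_spec`, :func:`reference_unet3_spec` and
:func:`reference_discriminator_spec` hold the package's reference
configurations, whose combined trainable-parameter totals act as checksums
for the two published model sizes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .layers import (BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, Layer,
                     MaxPool2d, Param, ReLU, Sequential, Sigmoid)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_sunet_generator",
    "build_unet3_generator",
    "build_discriminator",
    "count_trainable_parameters",
    "he_initialize",
    "reference_sunet_spec",
    "reference_unet3_spec",
    "reference_discriminator_spec",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class GeneratorSpec:
    """Declarative description of a U-Net generator.

    ``stage_features`` lists the feature counts of the encoder stages
    followed by the bottleneck, so its length must be ``depth + 1``.
    """

    depth: int
    stage_features: Tuple[int, ...]
    convs_per_stage: int = 2
    kernel_size: int = 3
    in_channels: int = 1
    out_channels: int = 1
    use_batch_norm: bool = True
    bias: bool = True
    dropout_rate: float = 0.5
    up_kernel: int = 2
    final_kernel: int = 1

    def __post_init__(self) -> None:
        self.stage_features = tuple(int(f) for f in self.stage_features)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.stage_features) != self.depth + 1:
            raise ValueError(
                f"stage_features must have depth+1={self.depth + 1} entries, "
                f"got {len(self.stage_features)}")
        if any(f <= 0 for f in self.stage_features):
            raise ValueError("feature counts must be positive")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class DiscriminatorSpec:
    """Three conv/batch-norm/ReLU blocks, a final convolution, a sigmoid."""

    block_features: Tuple[int, ...]
    kernel_size: int = 4
    stride: int = 2
    conditional: bool = True
    bias: bool = True
    batch_norm_first_block: bool = True
    final_kernel: int = 1

    def __post_init__(self) -> None:
        self.block_features = tuple(int(f) for f in self.block_features)
        if len(self.block_features) != 3:
            raise ValueError("the discriminator has exactly 3 blocks")
        if any(f <= 0 for f in self.block_features):
            raise ValueError("feature counts must be positive")

    @property
    def in_channels(self) -> int:
        return 2 if self.conditional else 1


def _conv_block(cin: int, cout: int, spec: GeneratorSpec) -> List[Layer]:
    layers: List[Layer] = [Conv2d(cin, cout, spec.kernel_size, bias=spec.bias)]
    if spec.use_batch_norm:
        layers.append(BatchNorm2d(cout))
    layers.append(ReLU())
    return layers


class UNetGenerator(Layer):
    """Encoder/decoder U-Net with skip concatenations.

    Decoder stages run an up-convolution, concatenate the up-sampled features
    with the matching encoder output (up-sampled first, skip second along the
    channel axis), then apply the stage's conv blocks and dropout.
    """

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        d = spec.depth
        feats = spec.stage_features

        self.enc_stages: List[Sequential] = []
        cin = spec.in_channels
        for f in feats[:d]:
            layers: List[Layer] = []
            for i in range(spec.convs_per_stage):
                layers.extend(_conv_block(cin if i == 0 else f, f, spec))
            self.enc_stages.append(Sequential(*layers))
            cin = f
        self.pools = [MaxPool2d(2) for _ in range(d)]

        layers = []
        for i in range(spec.convs_per_stage):
            layers.extend(_conv_block(cin if i == 0 else feats[d], feats[d], spec))
        self.bottleneck = Sequential(*layers)
        cin = feats[d]

        self.upconvs: List[ConvTranspose2d] = []
        self.dec_stages: List[Sequential] = []
        self.dropouts: List[Dropout] = []
        for f in reversed(feats[:d]):
            self.upconvs.append(ConvTranspose2d(cin, f, spec.up_kernel, bias=spec.bias))
            layers = []
            for i in range(spec.convs_per_stage):
                layers.extend(_conv_block(2 * f if i == 0 else f, f, spec))
            self.dec_stages.append(Sequential(*layers))
            self.dropouts.append(Dropout(spec.dropout_rate))
            cin = f
        self.final = Conv2d(cin, spec.out_channels, spec.final_kernel, bias=True)

    # -- plumbing -----------------------------------------------------------
    def params(self) -> List[Param]:
        out: List[Param] = []
        for stage in self.enc_stages:
            out.extend(stage.params())
        out.extend(self.bottleneck.params())
        for up, dec in zip(self.upconvs, self.dec_stages):
            out.extend(up.params())
            out.extend(dec.params())
        out.extend(self.final.params())
        return out

    def forward(self, x, train=True, rng=None):
        d = self.spec.depth
        h, w = x.shape[2], x.shape[3]
        if h % (1 << d) or w % (1 << d):
            raise ValueError(
                f"in-plane size {(h, w)} not divisible by 2**depth = {1 << d}")
        skips = []
        for stage, pool in zip(self.enc_stages, self.pools):
            x = stage.forward(x, train=train, rng=rng)
            skips.append(x)
            x = pool.forward(x, train=train, rng=rng)
        x = self.bottleneck.forward(x, train=train, rng=rng)
        self._skip_channels = []
        for up, dec, drop, skip in zip(self.upconvs, self.dec_stages,
                                       self.dropouts, reversed(skips)):
            x = up.forward(x, train=train, rng=rng)
            self._skip_channels.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = dec.forward(x, train=train, rng=rng)
            x = drop.forward(x, train=train, rng=rng)
        return self.final.forward(x, train=train, rng=rng)

    def backward(self, grad):
        grad = self.final.backward(grad)
        skip_grads = []
        # walk decoder in reverse application order
        for i in range(len(self.dec_stages) - 1, -1, -1):
            grad = self.dropouts[i].backward(grad)
            grad = self.dec_stages[i].backward(grad)
            c_up, c_skip = self._skip_channels[i]
            grad, skip_grad = grad[:, :c_up], grad[:, c_up:]
            skip_grads.append(skip_grad)
            grad = self.upconvs[i].backward(grad)
        # encoder in reverse, adding the matching skip gradient
        skip_grads = skip_grads[::-1]  # now indexed like enc_stages via reversal
        grad = self.bottleneck.backward(grad)
        for j in range(len(self.enc_stages) - 1, -1, -1):
            grad = self.pools[j].backward(grad)
            # decoder stage i consumes skip of encoder stage depth-1-i
            grad = grad + skip_grads[len(self.enc_stages) - 1 - j]
            grad = self.enc_stages[j].backward(grad)
        return grad


class PatchDiscriminator(Sequential):
    """Conditional discriminator producing a patch score map in [0, 1]."""

    def __init__(self, spec: DiscriminatorSpec):
        self.spec = spec
        layers: List[Layer] = []
        cin = spec.in_channels
        for i, f in enumerate(spec.block_features):
            layers.append(Conv2d(cin, f, spec.kernel_size, stride=spec.stride,
                                 bias=spec.bias))
            if spec.batch_norm_first_block or i > 0:
                layers.append(BatchNorm2d(f))
            layers.append(ReLU())
            cin = f
        layers.append(Conv2d(cin, 1, spec.final_kernel, bias=True))
        layers.append(Sigmoid())
        super().__init__(*layers)

    def forward(self, x, train=True, rng=None):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"discriminator expects {self.spec.in_channels} channels, "
                f"got {x.shape[1]}")
        return super().forward(x, train=train, rng=rng)


# ---------------------------------------------------------------------------
# builders, counting, initialization
# ---------------------------------------------------------------------------

def build_sunet_generator(spec: GeneratorSpec) -> UNetGenerator:
    """Build the shallow (depth-2) U-Net generator."""
    if spec.depth != 2:
        raise ValueError(f"the shallow U-Net has depth 2, spec says {spec.depth}")
    return UNetGenerator(spec)


def build_unet3_generator(spec: GeneratorSpec) -> UNetGenerator:
    """Build the benchmark depth-3 U-Net generator."""
    if spec.depth != 3:
        raise ValueError(f"the benchmark U-Net has depth 3, spec says {spec.depth}")
    return UNetGenerator(spec)


def build_discriminator(spec: DiscriminatorSpec) -> PatchDiscriminator:
    return PatchDiscriminator(spec)


def count_trainable_parameters(*nets: Layer) -> int:
    """Total size of all trainable tensors across the given networks.

    Convolution and up-convolution weights and biases and batch-norm
    scale/offset pairs count; batch-norm running statistics do not.
    """
    return sum(p.size for net in nets for p in net.params())


def he_initialize(net: Layer, seed: int) -> Layer:
    """He-normal initialization of every (up-)convolution weight, in place.

    Weights are drawn from N(0, 2 / fan_in) with fan_in the kernel area
    times the input channel count; biases start at zero, batch-norm at the
    identity.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    for p in net.params():
        if p.name.endswith("weight"):
            if p.value.ndim != 4:
                raise ValueError(f"unexpected weight shape {p.value.shape}")
            k_area = p.value.shape[2] * p.value.shape[3]
            if p.name.startswith("upconv"):
                fan_in = p.value.shape[0] * k_area   # (cin, cout, k, k)
            else:
                fan_in = p.value.shape[1] * k_area   # (cout, cin, k, k)
            p.value[...] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=p.value.shape)
        elif p.name.endswith("bias") or p.name.endswith("offset"):
            p.value[...] = 0.0
        elif p.name.endswith("scale"):
            p.value[...] = 1.0
    return net


# ---------------------------------------------------------------------------
# reference architectures (populated from the checksum search; see
# docs/methods.md for how these configurations were pinned down)
# ---------------------------------------------------------------------------

_REFERENCE_SUNET_FEATURES: Tuple[int, ...] = (64, 128, 256)
_REFERENCE_UNET3_FEATURES: Tuple[int, ...] = (44, 128, 204, 216)
_REFERENCE_DISC: dict = {
    "block_features": (84, 248, 496),
    "kernel_size": 3,
    "stride": 2,
    "conditional": True,
    "bias": True,
    "batch_norm_first_block": False,
    "final_kernel": 1,
}


def reference_sunet_spec(dropout_rate: float = 0.5) -> GeneratorSpec:
    """Reference shallow-generator architecture (checksum 3,163,142 with the
    reference discriminator)."""
    return GeneratorSpec(depth=2, stage_features=_REFERENCE_SUNET_FEATURES,
                         dropout_rate=dropout_rate)


def reference_unet3_spec(dropout_rate: float = 0.5) -> GeneratorSpec:
    """Reference benchmark-generator architecture (checksum 4,868,614 with the
    reference discriminator)."""
    return GeneratorSpec(depth=3, stage_features=_REFERENCE_UNET3_FEATURES,
                         dropout_rate=dropout_rate)


def reference_discriminator_spec() -> DiscriminatorSpec:
    return DiscriminatorSpec(**_REFERENCE_DISC)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, generator: UNetGenerator,
                    discriminator: Optional[PatchDiscriminator] = None) -> Path:
    """Save network weights plus their specs in one self-describing .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    meta = {"generator_spec": asdict(generator.spec)}
    for i, p in enumerate(generator.params()):
        arrays[f"g_{i}"] = p.value
    if discriminator is not None:
        meta["discriminator_spec"] = asdict(discriminator.spec)
        for i, p in enumerate(discriminator.params()):
            arrays[f"d_{i}"] = p.value
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path) -> Tuple[UNetGenerator, Optional[PatchDiscriminator]]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        gen = UNetGenerator(GeneratorSpec(**meta["generator_spec"]))
        for i, p in enumerate(gen.params()):
            p.value[...] = data[f"g_{i}"]
        disc = None
        if "discriminator_spec" in meta:
            disc = PatchDiscriminator(DiscriminatorSpec(**meta["discriminator_spec"]))
            for i, p in enumerate(disc.params()):
                p.value[...] = data[f"d_{i}"]
    return gen, disc
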