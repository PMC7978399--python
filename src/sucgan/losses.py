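"""Adversarial and L1 training objectives.

The discriminator minimizes the usual binary cross-entropy form of the
conditional-GAN value function; the generator minimizes the non-saturating
``-log D(G(y))`` surrogate plus an L1 reconstruction term weighted by
``lambda``.  Scores are clamped away from {0, 1} before logarithms.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EPS",
    "l1_term",
    "discriminator_loss",
    "generator_adversarial_loss",
    "total_generator_loss",
]

#: score clamp used before any logarithm
EPS = 1e-7


def _clamp(score: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(score, dtype=np.float64), EPS, 1.0 - EPS)


def l1_term(x: np.ndarray, gx: np.ndarray) -> float:
    """Mean absolute difference between a real slice and a generated one."""
    x, gx = np.asarray(x), np.asarray(gx)
    if x.shape != gx.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {gx.shape}")
    return float(np.mean(np.abs(x - gx)))


def discriminator_loss(d_real, d_fake) -> float:
    """``-[mean log D(x|y) + mean log(1 - D(G(y)|y))]`` over the score maps."""
    d_real, d_fake = _clamp(d_real), _clamp(d_fake)
    return float(-(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake))))


def generator_adversarial_loss(d_fake) -> float:
    """Non-saturating generator surrogate ``-mean log D(G(y)|y)``."""
    return float(-np.mean(np.log(_clamp(d_fake))))


def total_generator_loss(adv: float, l1: float, lambda_l1: float) -> float:
    """Generator objective: adversarial term plus ``lambda * L1``."""
    return float(adv) + float(lambda_l1) * float(l1)


# ---------------------------------------------------------------------------
# analytic gradients with respect to the raw score maps, used by the trainer
# ---------------------------------------------------------------------------

def _grad_log(score: np.ndarray) -> np.ndarray:
    """d/ds of mean(log clamp(s)); zero where the clamp is active."""
    s = np.asarray(score, dtype=np.float64)
    inside = (s > EPS) & (s < 1.0 - EPS)
    g = np.zeros_like(s)
    g[inside] = 1.0 / (s[inside] * s.size)
    return g


def grad_discriminator_loss(d_real, d_fake):
    """Gradients of :func:`discriminator_loss` wrt the two score maps."""
    return -_grad_log(d_real), _grad_log(1.0 - np.asarray(d_fake))


def grad_generator_adversarial_loss(d_fake):
    """Gradient of :func:`generator_adversarial_loss` wrt the fake score map."""
    return -_grad_log(d_fake)


def grad_l1_term(x, gx):
    """Gradient of :func:`l1_term` with respect to the generated slice."""
    x, gx = np.asarray(x), np.asarray(gx)
    return np.sign(gx - x) / x.size
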