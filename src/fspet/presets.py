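"""Desk-scale training presets.

The reference recipe (512x512 slices, 30 epochs, generator/discriminator
learning rate 1e-4) assumes GPU-scale throughput. The presets here are
the package's CPU-friendly study conditions: 128x128 slices, one quarter
of the epochs for the adversarial phase, and learning rates scaled up to
compensate for the ~40x smaller number of optimizer steps, with the
discriminator stepped more gently than the generator (lr/4) so it cannot
collapse the generator's learning signal early. The loss weights
(lambda1 = 1e-2, lambda2 = 1e-4) and the auto-encoder recipe
(lr 0.01, 30 epochs, batch 32) are unchanged. Rationale and sensitivity
notes live in docs/methods.md.
"""

from __future__ import annotations

from .adversarial import GANConfig, LossWeights
from .cae import CAEConfig

__all__ = ["desk_cae_config", "desk_gan_config"]


def desk_cae_config(seed: int = 0, epochs: int = 30) -> CAEConfig:
    """Auto-encoder preset: the reference recipe already fits a CPU."""
    return CAEConfig(seed=seed, epochs=epochs)


def desk_gan_config(seed: int = 0, epochs: int = 10, depth: int = 4,
                    adversarial: bool = True,
                    weights: LossWeights | None = None) -> GANConfig:
    """Adversarial-phase preset for 128x128 (depth 4) or 64x64 (depth 3)."""
    return GANConfig(lr=2e-3, d_lr=5e-4, epochs=epochs, depth=depth,
                     base_filters=8, d_base_filters=8,
                     adversarial=adversarial,
                     weights=weights if weights is not None else LossWeights(),
                     seed=seed)
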