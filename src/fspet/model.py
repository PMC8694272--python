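"""Model/Results facade over the two-phase training pipeline.

``FSPET`` is constructed from a paired dataset (plus an optional
independent population of prior masks) and a configuration; ``fit()``
runs the two training phases in the required order — the convolutional
auto-encoder on the shape priors first, then the adversarial
generator/discriminator pair with the frozen encoder as latent
regularizer — and returns an ``FSPETResults`` carrying the trained
networks, the loss history of both phases and evaluation helpers.

    >>> model = FSPET.from_phantom(PhantomParams(), n_train=200, n_test=50,
    ...                            seed=0)
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import dataclasses

from .adversarial import (DiscriminatorModel, GeneratorModel, predict_mask,
                          train_fspet)
from .cae import CAEModel, train_cae
from .config import RunConfig
from .data_io import BinaryMask, PairedDataset
from .exceptions import ConfigurationError
from .metrics import MetricReport, evaluate_dataset
from .phantom import PhantomParams, generate_dataset, split_dataset

__all__ = ["FSPET", "FSPETResults"]


class FSPET:
    """The fused segmentation model, before fitting.

    Parameters
    ----------
    dataset:
        Paired (slice, mask) data with train/val/test split tags.
    prior_masks:
        Shape-prior mask population for the CAE. Defaults to the
        ground-truth masks of the training split (the usual situation
        when one annotated corpus provides both roles).
    config:
        A :class:`RunConfig`; its ``cae`` and ``gan`` sections control
        the two phases. ``gan.weights.lambda2 = 0`` disables the prior
        (cGAN-Unet ablation); additionally ``gan.adversarial = False``
        gives plain U-net training.
    """

    def __init__(self, dataset: PairedDataset,
                 prior_masks: list[BinaryMask] | None = None,
                 config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.dataset = dataset
        train = dataset.subset("train")
        if len(train) == 0:
            raise ConfigurationError("dataset has no training split")
        self.train_data = train
        if prior_masks is None:
            prior_masks = [m for _, m in train.pairs]
        self.prior_masks = prior_masks

    @classmethod
    def from_phantom(cls, params: PhantomParams | None = None,
                     n_train: int = 200, n_val: int = 0, n_test: int = 50,
                     seed: int = 0, config: RunConfig | None = None) -> "FSPET":
        """Build the model on a freshly generated phantom corpus."""
        config = config or RunConfig()
        config.seed = seed
        config.n_train, config.n_val, config.n_test = n_train, n_val, n_test
        if params is not None:
            config.phantom = dataclasses.replace(params, seed=seed)
        config.cae.seed = seed
        config.gan.seed = seed
        n = n_train + n_val + n_test
        ds = split_dataset(generate_dataset(config.phantom, n, seed),
                           n_train, n_val, n_test)
        return cls(ds, config=config)

    def fit(self, cae: CAEModel | None = None) -> "FSPETResults":
        """Run CAE pre-training (unless a frozen CAE is supplied) and the
        alternating adversarial phase."""
        cae_history: list[float] = []
        needs_prior = self.config.gan.weights.lambda2 > 0
        if cae is None and needs_prior:
            cae, cae_history = train_cae(self.prior_masks, self.config.cae)
        gen, disc, history = train_fspet(self.train_data, cae, self.config.gan)
        return FSPETResults(self, gen, disc, cae, cae_history, history)


class FSPETResults:
    """Trained networks plus training history and evaluation helpers."""

    def __init__(self, model: FSPET, generator: GeneratorModel,
                 discriminator: DiscriminatorModel, cae: CAEModel | None,
                 cae_history: list[float], gan_history: list[dict]):
        self.model = model
        self.generator = generator
        self.discriminator = discriminator
        self.cae = cae
        self.cae_history = cae_history
        self.gan_history = gan_history
        self._reports: dict[str, MetricReport] = {}

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def predict(self, image, threshold: float | None = None) -> BinaryMask:
        thr = threshold if threshold is not None \
            else self.config.eval.threshold
        return predict_mask(self.generator, image, threshold=thr)

    def evaluate(self, data: PairedDataset | None = None,
                 split: str = "test") -> MetricReport:
        """Score the generator on a split of the model's dataset (default
        test) or on explicitly supplied paired data."""
        if data is None:
            data = self.model.dataset.subset(split)
            key = split
        else:
            key = None
        if key and key in self._reports:
            return self._reports[key]
        report = evaluate_dataset(self.generator, data,
                                  threshold=self.config.eval.threshold)
        if key:
            self._reports[key] = report
        return report

    def history_table(self):
        import pandas as pd
        return pd.DataFrame(self.gan_history)

    def summary(self) -> str:
        """Human-readable account of the fit: configuration, final losses
        and (if a test split exists) test metrics in mean ± std form."""
        cfg = self.config
        w = cfg.gan.weights
        variant = ("fspet" if (cfg.gan.adversarial and w.lambda2 > 0)
                   else "cgan-unet" if cfg.gan.adversarial else "unet")
        lines = [
            "FSPET fit summary",
            "=================",
            f"variant:          {variant} "
            f"(adversarial={cfg.gan.adversarial}, lambda1={w.lambda1}, "
            f"lambda2={w.lambda2})",
            f"seed:             {cfg.seed}",
            f"training pairs:   {len(self.model.train_data)}",
            f"image size:       {self.model.train_data[0][0].height}",
            f"gan epochs:       {cfg.gan.epochs} (lr {cfg.gan.lr})",
        ]
        if self.cae_history:
            lines.append(
                f"cae:              latent_dim {self.cae.latent_dim}, "
                f"{len(self.cae_history)} epochs, "
                f"final BCE {self.cae_history[-1]:.4f}")
        if self.gan_history:
            h = self.gan_history[-1]
            lines.append(
                "final losses:     "
                f"Ld {h['Ld']:.4f} | Lu {h['Lu']:.4f} | Le {h['Le']:.4f} | "
                f"LG {h['LG']:.4f} | LD {h['LD']:.4f}")
        if any(s == "test" for s in self.model.dataset.split):
            rep = self.evaluate(split="test")
            lines.append("test metrics:     " + rep.summary())
        return "\n".join(lines)
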