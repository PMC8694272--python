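"""Generator/discriminator contracts, loss algebra, trainer invariants."""

import math

import numpy as np
import pytest

from fspet.adversarial import (DiscriminatorModel, GANConfig, GeneratorModel,
                               LossWeights, adversarial_g_loss, dice_loss,
                               discriminator_loss, generator_total_loss,
                               predict_mask, train_fspet)
from fspet.cae import CAEConfig, CAEModel
from fspet.data_io import BinaryMask, PairedDataset, ImageSlice
from fspet.exceptions import ConfigurationError, DataError
from fspet.phantom import PhantomParams, generate_dataset

EPS = 1e-7


class StubD:
    """Discriminator stand-in returning a fixed probability."""

    def __init__(self, p):
        self.p = p

    def prob(self, images, masks):
        return np.full(np.asarray(masks).shape[0] if np.asarray(masks).ndim == 4
                       else 1, self.p)


def _frozen_cae(size=32):
    model = CAEModel(size, CAEConfig(latent_dim=8, base_filters=2, stages=2,
                                     seed=0))
    model.freeze()
    return model


# ---------------------------------------------------------------------------
# generator forward contracts

def test_generator_shape_range_determinism():
    gen = GeneratorModel(depth=2, base_filters=4, seed=0)
    rng = np.random.default_rng(0)
    x = rng.uniform(size=(2, 1, 32, 32))
    p1 = gen.forward(x)
    p2 = gen.forward(x)
    assert p1.shape == (2, 1, 32, 32)
    assert p1.min() >= 0.0 and p1.max() <= 1.0
    np.testing.assert_array_equal(p1, p2)


def test_generator_rejects_indivisible_dims_with_padding_hint():
    gen = GeneratorModel(depth=2, base_filters=4, seed=0)
    with pytest.raises(DataError, match="pad"):
        gen.forward(np.zeros((1, 1, 34, 34)))


def test_predict_mask_threshold_validation_and_tie_rule():
    gen = GeneratorModel(depth=2, base_filters=4, seed=0)

    class HalfG(GeneratorModel):
        def forward(self, images, train=False):
            return np.full((1, 1, 32, 32), 0.5)

    half = HalfG(depth=2, base_filters=4, seed=0)
    out = predict_mask(half, np.zeros((32, 32)), threshold=0.5)
    assert isinstance(out, BinaryMask)
    assert np.all(out.pixels == 1)  # ties >= threshold are foreground
    with pytest.raises(ValueError):
        predict_mask(gen, np.zeros((32, 32)), threshold=1.5)


# ---------------------------------------------------------------------------
# loss functions

def test_dice_loss_limits_and_hand_example():
    y = np.zeros((16, 16))
    y[2:6, 2:6] = 1
    assert dice_loss(y, y) == pytest.approx(0.0, abs=1e-6)
    assert dice_loss(np.ones((16, 16)),
                     np.zeros((16, 16))) == pytest.approx(1.0, abs=0.02)
    p = np.array([[1.0, 1.0, 0.0, 0.0]] * 8)
    t = np.array([[1.0, 0.0, 1.0, 0.0]] * 8)
    assert dice_loss(p, t, smooth=0.0) == pytest.approx(0.5)
    with pytest.raises(DataError):
        dice_loss(np.zeros((4, 4)), np.zeros((8, 8)))


def test_adversarial_g_loss_closed_forms():
    x = np.zeros((16, 16))
    p = np.zeros((16, 16))
    assert adversarial_g_loss(StubD(0.5), x, p) == pytest.approx(math.log(2))
    assert adversarial_g_loss(StubD(1.0), x, p) == pytest.approx(
        0.0, abs=1e-6)
    # fully rejected generator: clamped at eps, large but finite
    val = adversarial_g_loss(StubD(0.0), x, p)
    assert val == pytest.approx(-math.log(EPS))
    assert math.isfinite(val)


def test_discriminator_loss_closed_forms():
    x = y = p = np.zeros((16, 16))

    class TwoValD(StubD):
        def __init__(self, pr, pf):
            self.vals = [pr, pf]

        def prob(self, images, masks):
            return np.full(1, self.vals.pop(0))

    assert discriminator_loss(TwoValD(1.0, 0.0), x, y, p) == pytest.approx(
        0.0, abs=1e-5)
    assert discriminator_loss(TwoValD(0.5, 0.5), x, y, p) == pytest.approx(
        2 * math.log(2))
    assert discriminator_loss(TwoValD(EPS, 0.5), x, y, p) >= -math.log(EPS) - 1


def test_total_loss_is_weighted_sum_of_components():
    rng = np.random.default_rng(1)
    cae = _frozen_cae()
    d = DiscriminatorModel(32, base_filters=2, seed=0)
    w = LossWeights(lambda1=1e-2, lambda2=1e-4)
    for _ in range(5):
        x = rng.uniform(size=(32, 32))
        p = rng.uniform(size=(32, 32))
        y = (rng.uniform(size=(32, 32)) > 0.8).astype(float)
        total, parts = generator_total_loss(d, cae, x, p, y, w)
        from fspet.cae import latent_loss
        assert parts["Ld"] == pytest.approx(adversarial_g_loss(d, x, p))
        assert parts["Lu"] == pytest.approx(dice_loss(p, y))
        assert parts["Le"] == pytest.approx(latent_loss(cae, p, y))
        assert total == pytest.approx(
            parts["Ld"] + w.lambda1 * parts["Lu"] + w.lambda2 * parts["Le"],
            rel=1e-9)
        assert min(parts.values()) >= 0.0


def test_total_loss_degenerates_to_pure_adversarial():
    cae = _frozen_cae()
    d = DiscriminatorModel(32, base_filters=2, seed=0)
    rng = np.random.default_rng(2)
    x, p = rng.uniform(size=(32, 32)), rng.uniform(size=(32, 32))
    y = (rng.uniform(size=(32, 32)) > 0.8).astype(float)
    total, _ = generator_total_loss(d, cae, x, p, y, LossWeights(0.0, 0.0))
    assert total == pytest.approx(adversarial_g_loss(d, x, p))


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        LossWeights(lambda1=-0.1)
    with pytest.raises(ValueError):
        LossWeights(lambda2=-1.0)


# ---------------------------------------------------------------------------
# trainer

def _tiny_dataset(n=8, seed=0):
    params = PhantomParams(image_size=32, ribbon_thickness=3.0,
                           deformation_amplitude=1.0)
    return generate_dataset(params, n, seed=seed)


def test_epochs_zero_returns_initialized_models():
    ds = _tiny_dataset()
    cfg = GANConfig(epochs=0, depth=2, base_filters=4, d_base_filters=2,
                    weights=LossWeights(1e-2, 0.0), adversarial=True, seed=0)
    gen, disc, history = train_fspet(ds, None, cfg)
    assert history == []
    assert gen.forward(ds.images()).shape == (8, 1, 32, 32)


def test_training_history_records_all_components():
    ds = _tiny_dataset()
    cae = _frozen_cae()
    cfg = GANConfig(epochs=2, depth=2, base_filters=4, d_base_filters=2,
                    lr=1e-3, seed=0)
    gen, disc, history = train_fspet(ds, cae, cfg)
    assert len(history) == 2
    for row in history:
        assert {"Ld", "Lu", "Le", "LG", "LD"} <= set(row)
        assert row["LG"] == pytest.approx(
            row["Ld"] + cfg.weights.lambda1 * row["Lu"]
            + cfg.weights.lambda2 * row["Le"], rel=1e-5)


def test_trainer_requires_frozen_matching_cae():
    ds = _tiny_dataset()
    with pytest.raises(ConfigurationError):
        train_fspet(ds, None, GANConfig(epochs=1, depth=2))
    unfrozen = CAEModel(32, CAEConfig(latent_dim=8, base_filters=2, stages=2))
    with pytest.raises(ConfigurationError):
        train_fspet(ds, unfrozen, GANConfig(epochs=1, depth=2))
    wrong_size = _frozen_cae(size=64)
    with pytest.raises(ConfigurationError):
        train_fspet(ds, wrong_size, GANConfig(epochs=1, depth=2))


def _all_arrays(net):
    from fspet.checkpoint import _arrays
    return [a.copy() for a in _arrays(net)]


def test_discriminator_steps_never_touch_generator():
    """With the generator learning rate at zero, any change to generator
    state could only come from discriminator updates leaking through -
    it must stay bitwise identical."""
    ds = _tiny_dataset()
    cae = _frozen_cae()
    cfg = GANConfig(epochs=1, depth=2, base_filters=4, d_base_filters=2,
                    lr=0.0, d_lr=1e-3, batchnorm=False, seed=0)
    ref = GeneratorModel(2, 4, seed=0, batchnorm=False)
    fg = float(ds.masks().mean())  # trainer's head-bias initialization
    ref.net.head.b[:] = np.log(fg / (1.0 - fg))
    gen, disc, _ = train_fspet(ds, cae, cfg)
    for a, b in zip(_all_arrays(ref.net), _all_arrays(gen.net)):
        np.testing.assert_array_equal(a, b)


def test_generator_steps_never_touch_discriminator_or_cae():
    ds = _tiny_dataset()
    cae = _frozen_cae()
    cae_before = [a.copy() for a in
                  _all_arrays(cae.encoder) + _all_arrays(cae.decoder)]
    cfg = GANConfig(epochs=1, depth=2, base_filters=4, d_base_filters=2,
                    lr=1e-3, d_lr=0.0, batchnorm=False, seed=0)
    ref = DiscriminatorModel(32, base_filters=2, seed=0)
    gen, disc, _ = train_fspet(ds, cae, cfg)
    for a, b in zip(_all_arrays(ref.net), _all_arrays(disc.net)):
        np.testing.assert_array_equal(a, b)
    cae_after = _all_arrays(cae.encoder) + _all_arrays(cae.decoder)
    for a, b in zip(cae_before, cae_after):
        np.testing.assert_array_equal(a, b)


def test_short_training_improves_dice_loss():
    ds = _tiny_dataset(n=16)
    cfg = GANConfig(epochs=4, depth=2, base_filters=4, lr=2e-3,
                    adversarial=False, weights=LossWeights(1e-2, 0.0), seed=0)
    gen, _, history = train_fspet(ds, None, cfg)
    assert history[-1]["Lu"] < history[0]["Lu"]
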