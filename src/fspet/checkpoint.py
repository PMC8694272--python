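"""Checkpointing: models serialized to ``.npz`` with embedded config.

A checkpoint stores every learnable parameter *and* every batch-norm
running moment (in a deterministic walk order), plus a JSON header with
the constructor arguments and the training seed, so a reloaded model is
bit-identical in inference mode.
"""

from __future__ import annotations

import json

import numpy as np

from .adversarial import DiscriminatorModel, GeneratorModel
from .cae import CAEConfig, CAEModel
from .exceptions import FormatError
from .nn import BatchNorm2d, Sequential
from .nn.networks import UNet

__all__ = ["save_cae", "load_cae", "save_generator", "load_generator",
           "save_discriminator", "load_discriminator"]


def _iter_layers(net):
    if isinstance(net, Sequential):
        yield from net.layers
    elif isinstance(net, UNet):
        for m in net._modules():
            yield from _iter_layers(m)
    else:
        yield net


def _arrays(net) -> list[np.ndarray]:
    out = []
    for layer in _iter_layers(net):
        out.extend(layer.params)
        if isinstance(layer, BatchNorm2d):
            out.append(layer.running_mean)
            out.append(layer.running_var)
    return out


def _save(path: str, nets: dict, header: dict) -> None:
    payload = {"__header__": np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)}
    for name, net in nets.items():
        for i, arr in enumerate(_arrays(net)):
            payload[f"{name}:{i}"] = arr
    np.savez(path, **payload)


def _load(path: str) -> tuple[dict, dict]:
    try:
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            arrays: dict[str, list] = {}
            for key in z.files:
                if key == "__header__":
                    continue
                name, idx = key.rsplit(":", 1)
                arrays.setdefault(name, []).append((int(idx), z[key]))
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read checkpoint {path!r}: {exc}") from exc
    return header, {name: [a for _, a in sorted(v)] for name, v in arrays.items()}


def _restore(net, arrays: list[np.ndarray]) -> None:
    slots = _arrays(net)
    if len(slots) != len(arrays):
        raise FormatError(f"checkpoint has {len(arrays)} arrays, model "
                          f"expects {len(slots)}")
    for slot, arr in zip(slots, arrays):
        slot[...] = arr


def save_cae(model: CAEModel, path: str) -> None:
    cfg = model.config
    header = {"kind": "cae", "input_size": model.input_size,
              "frozen": model.frozen,
              "config": {"latent_dim": cfg.latent_dim,
                         "base_filters": cfg.base_filters,
                         "stages": cfg.stages, "lr": cfg.lr,
                         "epochs": cfg.epochs, "batch_size": cfg.batch_size,
                         "seed": cfg.seed}}
    _save(path, {"encoder": model.encoder, "decoder": model.decoder}, header)


def load_cae(path: str) -> CAEModel:
    header, arrays = _load(path)
    if header.get("kind") != "cae":
        raise FormatError(f"{path!r} is not a CAE checkpoint")
    model = CAEModel(header["input_size"], CAEConfig(**header["config"]))
    _restore(model.encoder, arrays["encoder"])
    _restore(model.decoder, arrays["decoder"])
    if header["frozen"]:
        model.freeze()
    return model


def save_generator(model: GeneratorModel, path: str, seed: int | None = None
                   ) -> None:
    header = {"kind": "generator", "depth": model.depth,
              "base_filters": model.base_filters,
              "batchnorm": model.batchnorm, "seed": seed}
    _save(path, {"net": model.net}, header)


def load_generator(path: str) -> GeneratorModel:
    header, arrays = _load(path)
    if header.get("kind") != "generator":
        raise FormatError(f"{path!r} is not a generator checkpoint")
    model = GeneratorModel(header["depth"], header["base_filters"],
                           batchnorm=header["batchnorm"])
    _restore(model.net, arrays["net"])
    for layer in _iter_layers(model.net):
        if isinstance(layer, BatchNorm2d):
            layer.freeze()
    return model


def save_discriminator(model: DiscriminatorModel, path: str,
                       seed: int | None = None) -> None:
    f = model.net.layers[0].W.shape[0]
    header = {"kind": "discriminator", "input_size": model.input_size,
              "base_filters": f, "seed": seed}
    _save(path, {"net": model.net}, header)


def load_discriminator(path: str) -> DiscriminatorModel:
    header, arrays = _load(path)
    if header.get("kind") != "discriminator":
        raise FormatError(f"{path!r} is not a discriminator checkpoint")
    model = DiscriminatorModel(header["input_size"], header["base_filters"])
    _restore(model.net, arrays["net"])
    return model
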