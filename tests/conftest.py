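"""Shared session fixtures: the desk-scale phantom corpus and the CAE
trained on it (reused by the auto-encoder fidelity and end-to-end
recovery tests, which study the same corpus)."""

import pytest

from fspet.cae import CAEConfig, train_cae
from fspet.phantom import PhantomParams, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def corpus128():
    """250 phantom pairs at 128x128 (contrast gap 0.15, blur 2, noise
    0.05), seed 0: 200 training + 50 held-out."""
    params = PhantomParams()
    ds = split_dataset(generate_dataset(params, 250, seed=0), 200, 0, 50)
    return params, ds


@pytest.fixture(scope="session")
def trained_cae128(corpus128):
    """Shape-prior CAE fitted on the 200 training masks with the
    reference recipe (Adam, lr 0.01, 30 epochs, batch 32)."""
    _, ds = corpus128
    return train_cae(ds.subset("train").masks(), CAEConfig(seed=0))
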