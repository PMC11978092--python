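"""Shared fixtures: a small synthetic bundle and a tiny model setup."""

from __future__ import annotations

import numpy as np
import pytest

from pathdrug import SimConfig, simulate
from pathdrug.experiments import build_dataset
from pathdrug.model import DrugResponseModel, ModelConfig


SMALL_SIM = SimConfig(
    n_genes=200,
    n_pathways=12,
    set_size_min=8,
    set_size_max=20,
    n_cell_lines=40,
    n_drugs=8,
    seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate(SMALL_SIM)


@pytest.fixture(scope="session")
def small_dataset(small_bundle):
    return build_dataset(small_bundle)


TINY_MODEL = dict(
    vocab_size=24,
    seq_len=16,
    embed_dim=8,
    conv_channels=8,
    transformer_heads=2,
    transformer_ff_dim=16,
    attention_dim=8,
    omics_dims={"expression": 6},
    mlp_hidden=(16,),
    dropout=0.1,
)


@pytest.fixture
def tiny_model():
    return DrugResponseModel(ModelConfig(seed=3, **TINY_MODEL))


@pytest.fixture
def tiny_inputs():
    rng = np.random.default_rng(11)
    codes = np.zeros((5, 16), dtype=int)
    for i in range(5):
        length = int(rng.integers(3, 12))
        codes[i, -length:] = rng.integers(1, 24, size=length)
    omics = {"expression": rng.normal(size=(5, 6)) ** 2}
    return codes, omics
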