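import numpy as np
import pytest

from maskmol import build_vocabulary
from maskmol.fixtures import (
    FixtureSpec,
    dataset_from_smiles,
    enumerate_small_molecules,
    split_smiles,
)
from maskmol.mgm_net import ModelConfig, init_parameters
from maskmol.train import TrainConfig, train_model


@pytest.fixture(scope="session")
def fixture_smiles():
    """Exhaustive <=4-heavy-atom C/N/O molecule set (desk-scale stand-in)."""
    return list(enumerate_small_molecules(FixtureSpec(4, ("C", "N", "O"))))


@pytest.fixture(scope="session")
def fixture_vocab(fixture_smiles):
    return build_vocabulary(fixture_smiles)


@pytest.fixture(scope="session")
def fixture_splits(fixture_smiles, fixture_vocab):
    train, valid = split_smiles(fixture_smiles, 0.15, seed=0)
    ds_train, _ = dataset_from_smiles(train, fixture_vocab, "train")
    ds_valid, _ = dataset_from_smiles(valid, fixture_vocab, "valid")
    return ds_train, ds_valid


@pytest.fixture(scope="session")
def tiny_vocab():
    return build_vocabulary(["C", "CCO", "CC=O", "C#N", "CNC", "c1ccccc1"])


@pytest.fixture(scope="session")
def tiny_model(tiny_vocab):
    cfg = ModelConfig(d0=16, n_layers=2)
    params = init_parameters(tiny_vocab, cfg, np.random.default_rng(0))
    return params, cfg


# ---------------------------------------------------------------------------
# shared trained models for the acceptance suite (trained once per session)
# ---------------------------------------------------------------------------

MEMO_TARGET = "CC(=O)O"


@pytest.fixture(scope="session")
def memorized_model():
    """d0=64, L=2 model overfit on one molecule within 500 optimizer steps."""
    vocab = build_vocabulary([MEMO_TARGET])
    ds, _ = dataset_from_smiles([MEMO_TARGET] * 32, vocab, "train")
    ds_valid, _ = dataset_from_smiles([MEMO_TARGET], vocab, "valid")
    cfg = ModelConfig(d0=64, n_layers=2)
    tcfg = TrainConfig(learning_rate=2e-2, batch_size=32, max_epochs=400, patience=400, seed=0)
    ckpt = train_model(ds, ds_valid, cfg, tcfg, vocab)
    return ckpt, vocab, ds_valid


@pytest.fixture(scope="session")
def fixture_model(fixture_splits, fixture_vocab):
    """d0=128, L=3 model trained on the exhaustive fixture set."""
    ds_train, ds_valid = fixture_splits
    cfg = ModelConfig(d0=128, n_layers=3)
    # two-stage schedule: plateau at 2e-3, then refine at 5e-4
    # (validation loss ~0.046 -> ~0.037 nats/slot)
    stage1 = train_model(
        ds_train, ds_valid, cfg,
        TrainConfig(learning_rate=2e-3, batch_size=64, max_epochs=150, patience=150, seed=0),
        fixture_vocab,
    )
    ckpt = train_model(
        ds_train, ds_valid, cfg,
        TrainConfig(learning_rate=5e-4, batch_size=64, max_epochs=60, patience=60, seed=1),
        fixture_vocab, init_params=stage1.params,
    )
    return ckpt


@pytest.fixture(scope="session")
def conditional_model(fixture_smiles, fixture_vocab):
    """Molecular-weight-conditioned model on the fixture set."""
    from rdkit.Chem import Descriptors

    train, valid = split_smiles(fixture_smiles, 0.15, seed=1)
    ds_train, _ = dataset_from_smiles(train, fixture_vocab, "train", property_fn=Descriptors.MolWt)
    ds_valid, _ = dataset_from_smiles(valid, fixture_vocab, "valid", property_fn=Descriptors.MolWt)
    cfg = ModelConfig(d0=96, n_layers=3, conditional=True, property_name="molwt")
    tcfg = TrainConfig(learning_rate=2e-3, batch_size=64, max_epochs=60, patience=15, seed=1)
    ckpt = train_model(ds_train, ds_valid, cfg, tcfg, fixture_vocab)
    return ckpt, ds_train
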