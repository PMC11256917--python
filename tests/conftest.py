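"""Shared fixtures.

The expensive trained-model fixtures are session-scoped and shared between
the training-behaviour tests and the acceptance tests, so each configuration
is trained exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from bsdti import (DTIModel, ModelConfig, SynthSpec, make_pairs,
                   train_val_split)
from bsdti.trainer import ablate

# ---------------------------------------------------------------- structures

#: three collinear residues, C-alpha spacing 3.8 A along x
PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      5  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

PDB_1RES = """\
ATOM      1  CA  TRP A   1       0.000   0.000   0.000  1.00  0.00           C
END
"""

#: two chains of two residues each; chain B close to chain A in space
PDB_2CHAIN = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LEU B   1       0.000   5.000   0.000  1.00  0.00           C
ATOM      4  CA  LYS B   2       3.800   5.000   0.000  1.00  0.00           C
END
"""

#: second residue lacks a C-alpha atom
PDB_NO_CA = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_3res():
    return PDB_3RES


@pytest.fixture
def pdb_1res():
    return PDB_1RES


@pytest.fixture
def pdb_2chain():
    return PDB_2CHAIN


@pytest.fixture
def pdb_no_ca():
    return PDB_NO_CA


# ------------------------------------------------------------ reduced configs
# Desk-scale study conditions used throughout the training tests: narrow
# widths (hidden 32, pooling scales 64/32/16/8, 64-dim decoder) on synthetic
# proteins of 48-72 residues, so a full training run takes about a minute of
# CPU rather than GPU-days.

def reduced_config(**overrides) -> ModelConfig:
    base = dict(hidden_dim=32, protein_scales=(64, 32, 16, 8),
                decoder_hidden=64, head_hidden=64, batch_size=128,
                max_epochs=15, patience=4, seed=0, dtype="float32")
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def planted_dataset():
    """The 2000-pair planted-motif dataset with 5% label noise."""
    return make_pairs(SynthSpec(seed=11))


@pytest.fixture(scope="session")
def planted_splits(planted_dataset):
    """80/20 train/test split, with 12.5% of train held out for validation
    (so the test set never steers early stopping)."""
    train_all, test = train_val_split(planted_dataset.dataset, 0.2, seed=101)
    train, val = train_val_split(train_all, 0.125, seed=102)
    return {"train": train, "val": val, "test": test}


SEEDS = (0, 1, 2)


def _train_variant(splits, flag, seed):
    cfg = reduced_config(seed=seed)
    model = ablate(cfg, flag) if flag else DTIModel(cfg)
    model.fit(splits["train"], splits["val"])
    scores = model.predict(splits["test"])["probability"].to_numpy()
    return model, scores


@pytest.fixture(scope="session")
def trained_full(planted_splits):
    """Full model trained on the planted dataset for each seed."""
    out = {}
    for seed in SEEDS:
        out[seed] = _train_variant(planted_splits, None, seed)
    return out


@pytest.fixture(scope="session")
def trained_no_mmsid(planted_splits):
    return {seed: _train_variant(planted_splits, "no_mmsid", seed)
            for seed in SEEDS}


@pytest.fixture(scope="session")
def trained_no_topk(planted_splits):
    return {seed: _train_variant(planted_splits, "no_topk", seed)
            for seed in SEEDS}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
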