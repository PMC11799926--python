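"""Shared fixtures.

The two end-to-end trainings (standard CBCT degradation and affine-only
degradation) are session-scoped: several tests interrogate the same trained
model, and training is by far the most expensive fixture.
"""

from __future__ import annotations

import numpy as np
import pytest

import adaptct as a

#: desk-scale study conditions: tiny preset, 20 phantom cases of 64x64x16,
#: 30 epochs, fixed seeds, lr 1e-3
N_CASES = 20
EPOCHS = 30
DATA_SEED = 11
MODEL_SEED = 0
LR = 1e-3


@pytest.fixture(scope="session")
def phantom_spec() -> a.PhantomSpec:
    return a.PhantomSpec()


@pytest.fixture(scope="session")
def phantom_case(phantom_spec):
    """One deterministic clean CT with its ground-truth masks."""
    ct = a.generate_thorax_ct(phantom_spec, seed=7)
    masks = a.thorax_masks(phantom_spec)
    return ct, masks


def train_cohort(art: a.ArtifactSpec):
    cases = a.generate_dataset(N_CASES, art=art, seed=DATA_SEED)
    model = a.build_model(a.TINY_PRESET, seed=MODEL_SEED)
    cfg = a.TrainConfig(learning_rate=LR, epochs=EPOCHS, seed=MODEL_SEED)
    model, history = a.train(model, cases, cfg)
    n_val = max(1, round(0.15 * len(cases)))
    return model, history, cases, cases[-n_val:]


@pytest.fixture(scope="session")
def trained_standard():
    """Model trained against the default degradation (drift + cupping +
    streaks + noise), with its cohort and held-out cases."""
    return train_cohort(a.ArtifactSpec())


@pytest.fixture(scope="session")
def trained_affine():
    """Model trained against a pure affine HU miscalibration."""
    return train_cohort(a.ArtifactSpec.affine_only())


def heldout_mae(model, val_cases):
    """Body-masked MAE of CBCT and synthesized CT against the planning CT,
    averaged over held-out cases."""
    mae_cbct, mae_act = [], []
    for c in val_cases:
        act = a.synthesize_volume(model, c.cbct)
        mae_cbct.append(a.mae(c.cbct, c.pct, c.body))
        mae_act.append(a.mae(act, c.pct, c.body))
    return float(np.mean(mae_cbct)), float(np.mean(mae_act))
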