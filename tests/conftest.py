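"""Shared fixtures.

Trained models are expensive (≈2 min each on one CPU), so the flagship
training runs are session-scoped and shared between the experiment-level
tests: 5 seeds of the standard interventional configuration plus shorter
paired runs (interventional vs none) for the training-effectiveness
comparison.
"""

from __future__ import annotations

import numpy as np
import pytest

import causalseg as cs

#: The study conditions of the flagship phantom experiment.
N_TRAIN, N_VAL = 32, 8
ACCEPTANCE_SEEDS = (0, 1, 2, 3, 4)


def make_cohorts(seed: int):
    spec = cs.PhantomSpec()
    train = cs.phantom.generate_cases(spec, N_TRAIN, 1000 + seed)
    val = cs.phantom.generate_cases(spec, N_VAL, 2000 + seed)
    return spec, train, val


def preprocessed(case, shape=(24, 24, 24)):
    vol, mask = cs.preprocess(case.volume, case.mask, target_shape=shape)
    return vol, mask


@pytest.fixture(scope="session")
def default_spec():
    return cs.PhantomSpec()


@pytest.fixture(scope="session")
def small_case(default_spec):
    return cs.generate_case(default_spec, seed=7)


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained deterministic tiny model (for shape/invariance tests)."""
    cfg = cs.TrainConfig(seed=0)
    return cs.CausalSegModel(cfg.backbone_config(), seed=0)


def _train_one(seed: int, **overrides):
    spec, train, val = make_cohorts(seed)
    cfg = cs.TrainConfig(seed=seed, **overrides)
    model, history = cs.fit(train, val, cfg)
    return {"spec": spec, "train": train, "val": val, "model": model,
            "history": history, "config": cfg}


@pytest.fixture(scope="session")
def trained_runs():
    """Flagship runs: one interventionally trained model per seed."""
    return {seed: _train_one(seed) for seed in ACCEPTANCE_SEEDS}


@pytest.fixture(scope="session")
def paired_short_runs():
    """Short paired runs (4 epochs): interventional (p=0.2) vs none (p=0),
    identical seeds and data, for the training-effectiveness ordering."""
    out = {}
    for seed in (0, 1, 2):
        out[seed] = {
            "p02": _train_one(seed, epochs=4),
            "p0": _train_one(seed, epochs=4, intervention_prob=0.0),
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
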