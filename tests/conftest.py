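"""Shared fixtures: phantoms and trained networks reused across the suite.

Training fixtures are session-scoped because network training is the
expensive step; all seeds are fixed so every run is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import colonseg as cs

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


RULE_PHANTOM_SEED = 11
TRUTH_PHANTOM_SEED = 101
TEST_PHANTOM_SEED = 7


def split_samples(samples, holdout_fraction=0.2, seed=5):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(samples))
    n_hold = int(len(samples) * holdout_fraction)
    hold = [samples[i] for i in idx[:n_hold]]
    train = [samples[i] for i in idx[n_hold:]]
    return train, hold


@pytest.fixture(scope="session")
def small_phantom():
    """A fast 3-slice, 128x128 phantom for smoke tests."""
    spec = cs.PhantomSpec(n_slices=3, slice_shape=(128, 128), lung_slice_range=(0, 1), seed=4)
    volume, truth = cs.generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def rule_training():
    """Rule-labeled window samples from 7 phantom slices, split 80/20."""
    spec = cs.PhantomSpec(n_slices=7, seed=RULE_PHANTOM_SEED)
    volume, _ = cs.generate_phantom(spec)
    samples = cs.build_training_set(volume, window=8)
    return split_samples(samples)


@pytest.fixture(scope="session")
def rule_net(rule_training):
    """Cascade network trained on the rule-labeled split."""
    train_samples, _ = rule_training
    net, report = cs.train(None, train_samples, cs.TrainConfig(max_epochs=600, seed=3))
    return net, report


@pytest.fixture(scope="session")
def truth_net():
    """Cascade network trained by slice-to-ground correlation (the
    pipeline's canonical supervision): windows overlapping any air, fluid
    or boundary ground truth are active; training windows are restricted
    to the body."""
    spec = cs.PhantomSpec(n_slices=7, seed=TRUTH_PHANTOM_SEED)
    volume, gt = cs.generate_phantom(spec)
    active = gt.colon_mask | gt.bowel_mask | gt.lung_mask | gt.fluid_mask | gt.pve_mask
    samples = cs.build_training_set(volume, window=8, truth=active, restrict=gt.body_mask)
    net, report = cs.train(None, samples, cs.TrainConfig(max_epochs=600, seed=3))
    return net, report


@pytest.fixture(scope="session")
def pipeline_run(truth_net):
    """Full pipeline over a fresh 20-slice phantom with the truth-trained net."""
    net, _ = truth_net
    spec = cs.PhantomSpec(n_slices=20, seed=TEST_PHANTOM_SEED)
    volume, gt = cs.generate_phantom(spec)
    states, finals = cs.run_pipeline(volume, net)
    return volume, gt, states, finals
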