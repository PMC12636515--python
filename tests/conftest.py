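"""Shared fixtures.

The two trained-model fixtures reproduce the package's reference study
conditions (balanced synthetic datasets with the default pathology and
misplacement magnitudes) and are session-scoped because training them is the
most expensive step in the suite.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from cardiopatch import iat, position, synth


@pytest.fixture(scope="session")
def clean_record_60bpm():
    """60 s clean record at exactly 60 bpm (deterministic RR grid)."""
    return synth.generate_record(
        rhythm=synth.RhythmModel(mean_hr=60, hr_sd=0, respiratory_mod_depth=0),
        fs=250.0, duration=60.0, seed=1)


@pytest.fixture(scope="session")
def default_record():
    return synth.generate_record(seed=3, duration=30.0)


@pytest.fixture(scope="session")
def iat_study():
    """The reference diagnosis study: 1000 balanced records (seed 7),
    stratified 80/20 split, default small transformer, trained to budget."""
    ds = synth.make_dataset(1000, seed=7, noise=synth.NoiseModel())
    X = iat.prepare_dataset(ds.records)
    cfg = iat.IATConfig(seed=7)
    t0 = time.time()
    model, weights = iat.train(None, ds.class_labels[ds.train_idx], cfg,
                               windows=X[ds.train_idx])
    train_seconds = time.time() - t0
    result = iat.evaluate(model, None, ds.class_labels[ds.test_idx],
                          windows=X[ds.test_idx])
    return {"dataset": ds, "windows": X, "config": cfg, "model": model,
            "weights": weights, "result": result,
            "train_seconds": train_seconds}


@pytest.fixture(scope="session")
def position_study():
    """The reference placement study: 600 records balanced over the three
    orientations (seed 11), default CNN+GRU net with discriminator."""
    ds = synth.make_dataset(600, seed=11, position_mix=(1 / 3, 1 / 3, 1 / 3),
                            noise=synth.NoiseModel())
    X = position.prepare_windows(ds.records)
    cfg = position.PositionNetConfig(seed=11)
    t0 = time.time()
    net, weights = position.train_position_net(
        None, ds.orientation_labels[ds.train_idx], cfg,
        windows=X[ds.train_idx])
    train_seconds = time.time() - t0
    result = position.evaluate_position(
        net, weights, None, ds.orientation_labels[ds.test_idx],
        windows=X[ds.test_idx])
    return {"dataset": ds, "windows": X, "config": cfg, "net": net,
            "weights": weights, "result": result,
            "train_seconds": train_seconds}


@pytest.fixture(scope="session")
def tiny_trained_models():
    """Small, fast models for pipeline plumbing tests (not for accuracy)."""
    ds = synth.make_dataset(80, seed=3, position_mix=(0.34, 0.33, 0.33),
                            noise=synth.NoiseModel())
    Xc = iat.prepare_dataset(ds.records)
    _, iw = iat.train(None, ds.class_labels[ds.train_idx],
                      iat.IATConfig(epochs=2, seed=1),
                      windows=Xc[ds.train_idx])
    Xp = position.prepare_windows(ds.records)
    _, pw = position.train_position_net(
        None, ds.orientation_labels[ds.train_idx],
        position.PositionNetConfig(epochs=2, seed=1),
        windows=Xp[ds.train_idx])
    return iw, pw
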