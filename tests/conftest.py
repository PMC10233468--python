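"""Shared fixtures: phantom datasets and scaled-down trained models.

The expensive fixtures are session-scoped and lazily built, so unit
tests that do not need a trained network never pay for one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from imcsr import datapipe as dp
from imcsr import phantoms as ph
from imcsr.network import ModelConfig, build_model
from imcsr.objective import LossWeights
from imcsr.trainer import TrainConfig, split_train_val, train

# frozen study conditions of the scaled-down two-class separation
# experiment: puncta vs filaments, high-SNR phantoms, 64x64 patches,
# tiny 2-group/2-block/16-feature model, 2000 Adam iterations at 1e-3
# (the iteration budget is ~100x smaller than a full-scale run, so the
# learning rate is scaled up accordingly)
EXPERIMENT_SEED = 1
PATCH_SIZE = 64
N_PAIRS = 240
TINY_CONFIG = ModelConfig(
    n_groups=2, n_blocks=2, n_features=16, reduction=4, in_channels=1, out_channels=2
)
TRAIN_CONFIG = TrainConfig(
    strategy="all",
    initial_lr=1e-3,
    lr_patience=10_000,
    batch_size=3,
    max_iterations=2_000,
    val_fraction=0.1,
    val_interval=200,
    seed=EXPERIMENT_SEED,
)


def build_two_class_pairs(seed: int = EXPERIMENT_SEED, n_pairs: int = N_PAIRS):
    """Phantom sources -> imaging -> patches -> superimposed pairs."""
    sources = {"puncta": [], "filament": []}
    for i in range(4):
        p = ph.make_puncta((192, 192), n_spots=22, radius=2.0, seed=seed * 100 + i)
        f = ph.make_filaments((192, 192), n_filaments=7, width=2.0, seed=seed * 200 + i)
        sources["puncta"].append(ph.apply_imaging(p, snr="high", seed=seed * 300 + i))
        sources["filament"].append(ph.apply_imaging(f, snr="high", seed=seed * 400 + i))
    patch_sets = {
        name: [
            patch
            for img in imgs
            for patch in dp.augment_patches(img, 30, PATCH_SIZE, seed=seed + j)
        ]
        for j, (name, imgs) in enumerate(sources.items())
    }
    return dp.build_dataset(patch_sets, n_pairs, seed=seed)


@dataclass
class PairExperiment:
    pairs: list
    val_set: list
    model_with_alpha: object
    model_without_alpha: object


@pytest.fixture(scope="session")
def pair_experiment() -> PairExperiment:
    """Two-class dataset plus two trained models (alpha = 0.02 and 0)."""
    pairs = build_two_class_pairs()
    _, val_set = split_train_val(pairs, TRAIN_CONFIG.val_fraction, TRAIN_CONFIG.seed)
    models = {}
    for alpha in (0.02, 0.0):
        model = build_model(TINY_CONFIG, seed=EXPERIMENT_SEED)
        best, _ = train(model, pairs, TRAIN_CONFIG, LossWeights(alpha=alpha))
        models[alpha] = best
    return PairExperiment(pairs, val_set, models[0.02], models[0.0])


@pytest.fixture(scope="session")
def tc_experiment():
    """A briefly-trained temporal-continuity model plus a moving test series."""
    seed = 7
    class_params = {
        "puncta": {"shape": (96, 96), "n_spots": 8, "radius": 2.0},
        "filament": {"shape": (96, 96), "n_filaments": 4},
    }
    samples = []
    for k in range(3):
        series = ph.make_time_series(class_params, n_frames=12, drift=0.8, seed=seed + k)
        samples.extend(dp.build_tc_samples(series))
    config = ModelConfig(
        n_groups=1, n_blocks=1, n_features=8, reduction=4, in_channels=3, out_channels=2
    )
    model = build_model(config, seed=seed)
    tcfg = TrainConfig(
        strategy="all",
        initial_lr=1e-3,
        batch_size=3,
        max_iterations=150,
        val_fraction=0.1,
        val_interval=50,
        seed=seed,
    )
    best, _ = train(model, samples, tcfg, LossWeights())
    test_series = ph.make_time_series(class_params, n_frames=8, drift=1.0, seed=seed + 100)
    moving_input = sum(
        np.stack([f.pixels for f in frames]) for frames in test_series.values()
    )
    return best, moving_input
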