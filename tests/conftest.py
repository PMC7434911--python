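"""Shared fixtures.

The expensive artefacts (the desk-scale study, the noisy-target retraining,
the CycleGAN seed sweep) are session-scoped so every test that needs them
shares one computation.
"""

import warnings

import numpy as np
import pytest

from vwdenoise.corruption import NoiseSpec
from vwdenoise.cyclegan import CycleGANConfig, train_cyclegan
from vwdenoise.experiment import ExperimentConfig, run_experiment
from vwdenoise.phantom import (PhantomSpec, generate_phantom, make_paired_dataset,
                               make_unpaired_dataset)
from vwdenoise.selfsup import TrainConfig, UNetConfig, train_denoiser

warnings.filterwarnings("ignore", message="degenerate", category=RuntimeWarning)

DESK_SEED = 1


def small_phantom_spec(seed=0, **overrides):
    base = dict(size=(64, 64), n_vessels=2, vessel_radius_range=(2.5, 4.5), seed=seed)
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def phantom_and_rois(small_spec):
    return generate_phantom(small_phantom_spec(seed=7))


@pytest.fixture(scope="session")
def desk_study():
    """The seeded desk-scale study: 200 training pairs, 20 epochs, 20 test phantoms."""
    return run_experiment(ExperimentConfig(seed=DESK_SEED))


@pytest.fixture(scope="session")
def desk_train_pairs():
    """The same 200-pair training set the desk study uses (regenerated cheaply)."""
    seeds = np.random.SeedSequence(DESK_SEED).generate_state(6) % (2 ** 31)
    return make_paired_dataset(200, small_phantom_spec(), NoiseSpec(), seed=int(seeds[0]))


@pytest.fixture(scope="session")
def noisy_target_model(desk_train_pairs):
    """The desk U-Net retrained with independently re-noised (never clean) targets."""
    seeds = np.random.SeedSequence(DESK_SEED).generate_state(6) % (2 ** 31)
    cfg = TrainConfig(seed=int(seeds[4]))
    return train_denoiser(desk_train_pairs, UNetConfig(depth=3, base_channels=8), cfg,
                          noisy_targets=True, noise_spec=NoiseSpec())


def micro_config(seed=3, out_dir=None):
    return ExperimentConfig(
        n_train=8, n_val=4, n_test=6, n_unpaired=4,
        selfsup_train=TrainConfig(epochs=2),
        cyclegan=CycleGANConfig(epochs=1),
        seed=seed, out_dir=out_dir,
    )


@pytest.fixture(scope="session")
def micro_summaries(tmp_path_factory):
    """The same micro-scale pipeline executed twice from one seed."""
    d1 = tmp_path_factory.mktemp("run1")
    d2 = tmp_path_factory.mktemp("run2")
    return (run_experiment(micro_config(out_dir=str(d1))),
            run_experiment(micro_config(out_dir=str(d2))),
            d1, d2)


@pytest.fixture(scope="session")
def cyclegan_seed_sweep():
    """Three short CycleGAN runs (seeds 0-2) on one 20+20 unpaired dataset."""
    data = make_unpaired_dataset(20, 20, small_phantom_spec(), NoiseSpec(),
                                 deform_magnitude=2.0, seed=5)
    models = [train_cyclegan(data, CycleGANConfig(epochs=8, seed=s)) for s in (0, 1, 2)]
    return data, models
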