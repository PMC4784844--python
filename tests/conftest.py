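"""Shared fixtures.

The expensive fixtures (surrogate ensemble, trained level-1/level-2 bases,
lesioned network, stimulus batteries) are session-scoped and computed once;
they back both the module-level post-training tests and the acceptance
suite.
"""

import numpy as np
import pytest

from hpcfill.blind_spot import apply_blind_spot, make_bs_mask
from hpcfill.experiments import normalize_responses, run_stimulus_battery
from hpcfill.model_core import HPCNetwork, NetworkParams
from hpcfill.preprocessing import TilingGeometry, preprocess_image
from hpcfill.synthetic_data import (
    BarSpec,
    make_nonlinearity_stimuli,
    make_training_ensemble,
    shifting_bar_battery,
)
from hpcfill.training import TrainConfig, train_level1, train_level2

# ---------------------------------------------------------------------------
# small random instance for gradient-oracle tests: U1 16x8 on 4x4 windows


@pytest.fixture()
def small_geometry():
    return TilingGeometry(patch_size=6, sub_size=4, overlap=2)


@pytest.fixture()
def small_network(small_geometry):
    rng = np.random.default_rng(11)
    mask = np.ones((6, 6))
    mask[2:4, 2:4] = 0.0
    return HPCNetwork(
        U1=rng.normal(size=(16, 8)),
        U2=rng.normal(size=(32, 5)),
        geometry=small_geometry,
        params=NetworkParams(),
        ff_mask=mask,
    )


@pytest.fixture()
def small_instance(small_network):
    rng = np.random.default_rng(12)
    patch = rng.normal(size=(6, 6))
    r1 = rng.normal(size=(4, 8))
    r2 = rng.normal(size=5)
    return patch, r1, r2


# ---------------------------------------------------------------------------
# session-scoped trained networks (reduced scale; see decisions ledger)

TRAIN_SEED = 1


@pytest.fixture(scope="session")
def training_images():
    return [
        preprocess_image(im, 200.0, 512)
        for im in make_training_ensemble(seed=0, size=256)
    ]


@pytest.fixture(scope="session")
def trained_level1(training_images):
    cfg = TrainConfig(n_batches=200, batch_size=50, seed=TRAIN_SEED)
    return train_level1(training_images, cfg)


@pytest.fixture(scope="session")
def trained_level2(training_images, trained_level1):
    cfg = TrainConfig(n_batches=120, batch_size=25, seed=TRAIN_SEED + 1, level=2)
    return train_level2(training_images, trained_level1.U, cfg)


@pytest.fixture(scope="session")
def level1_history(trained_level1):
    return trained_level1.history


@pytest.fixture(scope="session")
def level2_history(trained_level2):
    return trained_level2.history


@pytest.fixture(scope="session")
def trained_network(trained_level1, trained_level2):
    return HPCNetwork(U1=trained_level1.U, U2=trained_level2.U)


@pytest.fixture(scope="session")
def bs_mask():
    return make_bs_mask()


@pytest.fixture(scope="session")
def bs_network(trained_network, bs_mask):
    return apply_blind_spot(trained_network, bs_mask)


@pytest.fixture(scope="session")
def bar_spec():
    return BarSpec()


@pytest.fixture(scope="session")
def sweep_table(trained_network, bs_network, bar_spec):
    """Full 1-px shifting-bar sweep on both networks, normalized."""
    stimuli = shifting_bar_battery(bar_spec)
    table = run_stimulus_battery(
        {"non_bs": trained_network, "bs": bs_network}, stimuli
    )
    return normalize_responses(table)


@pytest.fixture(scope="session")
def nonlinearity_table(bs_network, bar_spec):
    stimuli = list(make_nonlinearity_stimuli(bar_spec).values())
    table = run_stimulus_battery({"bs": bs_network}, stimuli)
    return normalize_responses(table)
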