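import warnings

import numpy as np
import pandas as pd
import pytest

import ersp_attn as ea
from ersp_attn.pipeline import PipelineConfig, preprocess_recording

# the structurally-zero-variance baseline bin triggers an expected warning in
# every masking call; keep test output readable
warnings.filterwarnings(
    "ignore", message=".*zero across-trial variance.*", category=RuntimeWarning
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_roi_atlas(groups: dict[tuple[str, str], int]) -> ea.ElectrodeAtlas:
    full = ea.default_atlas()
    rows = [full.table.iloc[full.channels_in(h, r)[:n]] for (h, r), n in groups.items()]
    return ea.ElectrodeAtlas(pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="session")
def spl_atlas():
    """Four right-superior-parietal electrodes."""
    full = ea.default_atlas()
    idx = full.channels_in("R", "superior_parietal")[:4]
    return ea.ElectrodeAtlas(full.table.iloc[idx].reset_index(drop=True))


@pytest.fixture(scope="session")
def erd_simulation(spl_atlas):
    """120-trial spatial-condition recording with a known alpha ERD
    (power ratio 0.5, 400-600 ms, right SPL) plus 10% artifact epochs."""
    paradigm = ea.generate_paradigm("spatial", n_trials=125, n_targets=50, rng_seed=11)
    effect = ea.EffectSpec("R", "superior_parietal", "alpha", "ERD", 0.5, (400.0, 600.0))
    config = ea.SimulationConfig(
        atlas=spl_atlas, effects=(effect,), artifact_rate=0.1, rng_seed=11
    )
    recording, truth = ea.simulate_recording(paradigm, config)
    return recording, truth, effect


@pytest.fixture(scope="session")
def erd_epochs(erd_simulation):
    recording, truth, effect = erd_simulation
    epochs = preprocess_recording(PipelineConfig(trial_selection="all"), recording)
    return epochs, truth, effect


@pytest.fixture(scope="session")
def null_recording(spl_atlas):
    """No-effect, no-artifact stationary recording (100 trials)."""
    paradigm = ea.generate_paradigm("spatial", n_trials=100, n_targets=40, rng_seed=21)
    config = ea.SimulationConfig(atlas=spl_atlas, rng_seed=21)
    recording, _ = ea.simulate_recording(paradigm, config)
    return recording
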