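import numpy as np
import pytest

from smbench.emg_features import CHANNEL_SUBSETS, EmgTrial, FRAMES_PER_TRIAL
from smbench.synthetic_data import (
    default_synergy_model,
    generate_emg_dataset,
    generate_hand_template,
)


@pytest.fixture(scope="session")
def template():
    """Default-resolution (256 px panel) hand template."""
    return generate_hand_template(256)


@pytest.fixture(scope="session")
def small_template():
    """Coarse template for fast mask arithmetic tests."""
    return generate_hand_template(64)


@pytest.fixture(scope="session")
def synergy_model():
    return default_synergy_model(seed=0)


@pytest.fixture(scope="session")
def emg_trials(synergy_model):
    """One full prompted-posture dataset (32 postures x 10 reps, seed 0)."""
    return generate_emg_dataset(synergy_model, reps=10, seed=0)


def make_trial(wfl, posture=(0, 0, 0, 0), rep_index=1):
    """EmgTrial from an explicit channels x 100 WFL array."""
    return EmgTrial(posture=posture, rep_index=rep_index, wfl=np.asarray(wfl, float))


def flat_wfl(per_channel_levels, n_frames=FRAMES_PER_TRIAL):
    """Constant WFL frames with the given per-channel level."""
    levels = np.asarray(per_channel_levels, dtype=float)
    return np.repeat(levels[:, None], n_frames, axis=1)
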