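import numpy as np
import pytest

from cranioflow.synthdata import (
    NoiseModel,
    SceneConfig,
    default_combinations,
    default_timeline,
    generate_training_set,
    simulate_detection_log,
)


@pytest.fixture(scope="session")
def tiny_training_dir(tmp_path_factory):
    """Thirteen label-combination folders with 2 frames each."""
    out = tmp_path_factory.mktemp("data") / "training"
    generate_training_set(default_combinations(), 2, SceneConfig(seed=5), out, seed=5)
    return out


@pytest.fixture(scope="session")
def short_timeline():
    """An eleven-phase timeline over 660 frames (44 s at 15 fps)."""
    return default_timeline(660)


@pytest.fixture(scope="session")
def clean_log(short_timeline):
    """Noise-free simulated detection log for the short timeline."""
    return simulate_detection_log(short_timeline, NoiseModel(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
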