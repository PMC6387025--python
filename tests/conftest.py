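import numpy as np
import pytest

from wodwatch import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A reduced workout protocol for fast unit tests: 3 subjects, 3
    exercises, 5 reps per set, a short null recording."""
    return SyntheticConfig(
        n_subjects=3,
        exercises=("E1", "E2", "E3"),
        reps_per_set=5,
        null_duration_s=(10.0, 14.0),
        rest_between_sets_s=(3.0, 5.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sessions(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
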