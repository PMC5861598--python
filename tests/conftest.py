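import numpy as np
import pytest

from timeuse_coda import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def small_population():
    """A clean (uncorrupted) population of 300 participants."""
    cfg = GeneratorConfig(n_participants=300, seed=42)
    participants, diaries, truth = generate_population(cfg)
    return cfg, participants, diaries, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
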