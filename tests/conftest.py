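import numpy as np
import pytest

from palmotifs import (
    DiscoveryConfig,
    FrequencyMatrix,
    MotifDiscoveryModel,
    PlantConfig,
    generate_upstream_set,
)


def random_pwm(rng: np.random.Generator, width: int) -> FrequencyMatrix:
    """A random PWM with Dirichlet(0.5) columns."""
    return FrequencyMatrix(probs=rng.dirichlet(np.full(4, 0.5), size=width).T)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted promoter set: 80 x 120 bp, width-17 palindrome in 80%."""
    config = PlantConfig(n_sequences=80, seq_length=120, seed=11)
    upstream, truth = generate_upstream_set(config)
    return config, upstream, truth


@pytest.fixture(scope="session")
def quick_discovery(small_planted):
    """One discovery fit on the small planted set, shared across tests."""
    _, upstream, _ = small_planted
    config = DiscoveryConfig(
        min_width=15, max_width=19, n_motifs=1, n_starts=3, seed=7
    )
    return MotifDiscoveryModel(upstream, config).fit()
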