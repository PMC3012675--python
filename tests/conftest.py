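import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_gene():
    """Noiseless 2-transcript gene with an identifiable structure."""
    from isospace.synthetic import NoiseParams, SimulationConfig, simulate_gene

    cfg = SimulationConfig(n_samples=20, noise=NoiseParams(0.0, 0.0))
    return simulate_gene("cleangene", 2, cfg, seed=42)


@pytest.fixture
def noisy_gene():
    """Default-noise 3-transcript gene."""
    from isospace.synthetic import SimulationConfig, simulate_gene

    cfg = SimulationConfig(n_samples=33)
    return simulate_gene("noisygene", 3, cfg, seed=7)


def probeset_indices(gene):
    pos = {p: i for i, p in enumerate(gene.intensities.index)}
    return [np.array([pos[p] for p in probes]) for probes in gene.probesets.values()]
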