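import numpy as np
import pytest

from cnpdr import CorrelationDataset, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset() -> CorrelationDataset:
    """Deterministic 6-sample, 4-ROI dataset with hand-checkable values."""
    rng = np.random.default_rng(42)
    x = rng.uniform(-0.8, 0.8, size=(6, 6))
    phenotype = np.array([1, 1, 1, 0, 0, 0])
    return CorrelationDataset(x, ["A", "B", "C", "D"], phenotype)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with signal strong enough for smoke checks."""
    config = SimulationConfig(
        n_rois=20, n_cases=40, n_controls=40, n_functional=4, effect_size=2.0,
        multiway="max", seed=123,
    )
    return simulate_dataset(config)
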