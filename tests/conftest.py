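import numpy as np
import pytest

from pcdissect.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-stage cohort with known ground truth (session-cached)."""
    cfg = SimulationConfig(
        seed=42,
        n_samples_per_stage={"NBM": 3, "MGUS": 2, "SMM": 3, "MM": 2},
        cells_per_sample=(80, 120),
        n_genes=300,
        k_true=4,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
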