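import numpy as np
import pytest

from silistage import (
    SimulationConfig,
    filter_markers_by_missingness,
    generate_cohort,
    make_reference_fixture,
)


@pytest.fixture(scope="session")
def reference_cohort():
    """Deterministic cohort with the exact emulated study shape."""
    return make_reference_fixture(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small stochastic cohort with both modalities carrying signal."""
    cfg = SimulationConfig(
        n_patients=30, image_effect=1.2, biomarker_effect=0.8,
        feature_dim=24, seed=11,
    )
    cohort, gt = generate_cohort(cfg)
    cohort, _ = filter_markers_by_missingness(cohort)
    return cohort, gt


@pytest.fixture
def rng():
    return np.random.default_rng(42)
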