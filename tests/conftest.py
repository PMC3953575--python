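import numpy as np
import pytest

from cirrtex import ExperimentConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A single-sequence cohort small enough for repeated pipeline runs."""
    return generate_cohort(counts_per_stage=(6, 6, 6), sequences=("T1",),
                           rois_per_case_range=(2, 4), seed=11,
                           image_shape=(160, 160))


@pytest.fixture(scope="session")
def small_config():
    return ExperimentConfig(counts_per_stage=(6, 6, 6), sequences=("T1",),
                            rois_per_case_range=(2, 4),
                            image_shape=(160, 160)).reseeded(11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
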