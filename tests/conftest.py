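import numpy as np
import pytest

from plaquemorph import (
    SyntheticPlaqueParams,
    generate_cohort,
    generate_plaque_stack,
    measure_plaque,
)


@pytest.fixture(scope="session")
def clean_stack():
    """Noise-free synthetic plaque with its construction ground truth."""
    params = SyntheticPlaqueParams(noise_sd=0.0)
    return generate_plaque_stack(params, seed=11)


@pytest.fixture(scope="session")
def clean_measurements(clean_stack):
    stack, truth = clean_stack
    return measure_plaque(stack), truth


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(seed=7)
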