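import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from phqdaily import apply_sample_filters
from phqdaily.params import rating_count_probabilities
from phqdaily.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """Full-scale cohort in fixture mode (545 persons, exact rating counts)."""
    return generate_cohort(GeneratorConfig(seed=20240601))


@pytest.fixture(scope="session")
def fixture_tables(fixture_cohort):
    daily, panel, excl = apply_sample_filters(
        fixture_cohort.daily, fixture_cohort.panel
    )
    return daily, panel, excl


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (200 persons) for fast model-fitting tests."""
    cfg = GeneratorConfig(
        n_persons=200,
        cluster_size_distribution=rating_count_probabilities(),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    daily, panel, _ = apply_sample_filters(small_cohort.daily, small_cohort.panel)
    return daily, panel
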