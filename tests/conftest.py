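import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import moodscale as ms

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small clipped cohort with heterogeneous subjects."""
    config = ms.SimConfig(n_subjects=8, n_days=80, n_visits=5, seed=5)
    assessments, ratings, truth = ms.generate_cohort(config)
    return config, assessments, ratings, truth


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    _, assessments, ratings, _ = small_cohort
    return ms.assemble_dataset(assessments, ratings, "hdrs_total", "all", "min_rows:2")


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    """A quick hierarchical fit reused by prediction/importance tests."""
    sampler = ms.SamplerSpec(chains=2, warmup=200, draws=200, seed=9)
    return ms.fit_hierarchical(small_dataset, sampler=sampler, diagnostics=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
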