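import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def recovery_dataset():
    """400 trials from the three-mode ground-truth prior (weights
    0.5/0.3/0.2), simulated in the identifiable recovery regime with
    stationary (prior-drawn) seeds."""
    from rhythmprior.synthetic import (
        recovery_params,
        sample_prior_seeds,
        simulate_dataset,
        three_mode_prior,
    )

    g = np.random.default_rng(20240917)
    prior = three_mode_prior()
    seeds = sample_prior_seeds(prior, 400, g)
    return simulate_dataset(recovery_params(prior), 400, g, seeds=seeds)


@pytest.fixture(scope="session")
def recovery_kde(recovery_dataset):
    from rhythmprior.pipeline import fifth_iteration_point_sets
    from rhythmprior.prior_estimation import TrianglePriorKDE

    return TrianglePriorKDE().fit(fifth_iteration_point_sets(recovery_dataset))
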