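import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete simulated experiment shared across tests."""
    from tagcount.simulate import SimConfig, simulate_experiment

    config = SimConfig(
        seed=11,
        n_transcripts=12,
        n_samples_per_condition=3,
        baseline_mean=60.0,
        n_misprime_sites=2,
        error_rate=0.0,
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def small_pipeline_result(small_experiment):
    from tagcount.pipeline import run_pipeline

    exp = small_experiment
    return run_pipeline(
        exp.pairs,
        exp.genome,
        exp.annotations,
        exp.config.samples(),
        reference_lengths=exp.reference_lengths,
    )
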