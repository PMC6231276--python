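import hypothesis
import pytest

from asthmacost import GeneratorConfig, PipelineConfig, generate_cohort

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_windows():
    return PipelineConfig().windows


@pytest.fixture(scope="session")
def small_population():
    """500-patient synthetic population shared by read-only tests."""
    return generate_cohort(GeneratorConfig(n_patients=500, seed=42))
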