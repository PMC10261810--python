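import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def survey():
    """Synthetic 3 x 40-sample survey from the bundled reference moments."""
    from pcbrisk.datasets import product_moment_specs
    from pcbrisk.simulate import generate_survey

    return generate_survey(product_moment_specs(), n_per_product=40, seed=7)
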