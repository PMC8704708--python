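import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_bundle():
    """Noiseless 5-source fixture: every source equals the ground truth."""
    from fcdbkit.fixtures import FixtureSpec, generate_sources
    return generate_sources(FixtureSpec(
        n_sources=5, n_foods=30, n_components=25,
        noise_cv=0.0, zero_rate=0.0, outlier_rate=0.0, seed=7))


@pytest.fixture(scope="session")
def clean_foods(clean_bundle):
    from _helpers import run_pipeline
    foods, _report = run_pipeline(clean_bundle)
    return foods


@pytest.fixture(scope="session")
def noisy_bundle():
    """Reference noisy fixture with planted zeros and outliers."""
    from fcdbkit.fixtures import FixtureSpec, generate_sources
    return generate_sources(FixtureSpec(
        n_sources=7, n_foods=40, n_components=30, seed=11))
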