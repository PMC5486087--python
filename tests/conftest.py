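import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle():
    """The deterministic 94-patient bundle shared across integration tests."""
    from predictc.simulate import fixed_count_fixture

    return fixed_count_fixture()


@pytest.fixture(scope="session")
def fitted_fixture(fixture_bundle):
    """Full pipeline run on the deterministic bundle."""
    import warnings

    from predictc import PrediCTCModel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PrediCTCModel.from_dataframes(
            fixture_bundle.cq, fixture_bundle.clinical
        )
        return model.fit()
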