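import pytest
from hypothesis import HealthCheck, settings

from rosalnc.identify import run_cascade
from rosalnc.synthetic import SimConfig, generate

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic bundle shared across the suite."""
    return generate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    from rosalnc.synthetic import write_bundle

    d = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, d)
    return d


@pytest.fixture(scope="session")
def cascade(bundle):
    """(report, annotated, novel) from running the cascade on the bundle."""
    return run_cascade(
        bundle.transcripts,
        bundle.annotation,
        bundle.hits,
        bundle.sequences,
        bundle.cpc_scores,
    )
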