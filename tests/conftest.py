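import pytest
from hypothesis import HealthCheck, settings

from uvigkit.fixtures import make_fixture_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A full synthetic input bundle shared across CLI/pipeline tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    return make_fixture_bundle(outdir, seed=1)
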