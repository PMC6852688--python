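import pytest
from hypothesis import settings

from sctverbal.config import RunConfig
from sctverbal.fixtures import build_lupus_fixture, build_synthetic_fixture, default_fixture_spec
from sctverbal.pipeline import Engine
from sctverbal.terminology import load_rf2_dir

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lupus_dir(tmp_path_factory):
    return build_lupus_fixture(tmp_path_factory.mktemp("lupus"))


@pytest.fixture(scope="session")
def lupus_graph(lupus_dir):
    return load_rf2_dir(lupus_dir)


@pytest.fixture(scope="session")
def lupus_engine(lupus_dir):
    return Engine.from_config(RunConfig(rf2_dir=lupus_dir))


@pytest.fixture(scope="session")
def coverage_dir(tmp_path_factory):
    """Full-coverage synthetic terminology: every lexicon type on every disease."""
    return build_synthetic_fixture(
        default_fixture_spec(n_diseases=3, seed=7), tmp_path_factory.mktemp("coverage")
    )


@pytest.fixture(scope="session")
def coverage_engine(coverage_dir):
    return Engine.from_config(RunConfig(rf2_dir=coverage_dir))


@pytest.fixture(scope="session")
def large_dir(tmp_path_factory):
    """200 seeded synthetic diseases for the conservation/determinism suite."""
    return build_synthetic_fixture(
        default_fixture_spec(n_diseases=200, seed=3), tmp_path_factory.mktemp("large")
    )


@pytest.fixture(scope="session")
def large_engine(large_dir):
    return Engine.from_config(RunConfig(rf2_dir=large_dir))
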