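import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from primesim.io import load_configuration
from primesim.scenarios import (
    baseline_scenario,
    build_component_scenarios,
    default_targets,
)
from primesim.synthetic import make_test_fixture


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Miniature on-disk configuration (intake CSV, mortality CSV, params JSON)."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_test_fixture(seed=7, outdir=outdir)


@pytest.fixture(scope="session")
def fixture_config(fixture_paths):
    return load_configuration(*fixture_paths)


@pytest.fixture(scope="session")
def fixture_scenarios(fixture_config):
    """(baseline, component scenarios incl. the combined one)."""
    baseline = baseline_scenario(fixture_config)
    scenarios = build_component_scenarios(
        baseline, default_targets(fixture_config.components)
    )
    return baseline, scenarios
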