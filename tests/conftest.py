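import pytest

from tfdegrome import simulate


@pytest.fixture(scope="session")
def default_bundle():
    """The reference synthetic scenario (seed 1) shared across tests."""
    return simulate.generate_scenario(simulate.ScenarioParams())


@pytest.fixture(scope="session")
def scenario_dir(default_bundle, tmp_path_factory):
    """The reference scenario materialized to disk once per session."""
    d = tmp_path_factory.mktemp("scenario")
    simulate.materialize(default_bundle, d)
    return d
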