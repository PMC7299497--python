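import pytest

from triage_cim import (
    base_case_config,
    compare_scenarios,
    hostdx_config,
    run_scenario,
)


@pytest.fixture(scope="session")
def base_config():
    return base_case_config()


@pytest.fixture(scope="session")
def alt_config():
    return hostdx_config()


@pytest.fixture(scope="session")
def base_result(base_config):
    return run_scenario(base_config)


@pytest.fixture(scope="session")
def alt_result(alt_config):
    return run_scenario(alt_config)


@pytest.fixture(scope="session")
def comparison(base_result, alt_result):
    return compare_scenarios(base_result, alt_result)
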