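import pytest

from brnsim import ip3r_reference_network, run_all_scenarios


@pytest.fixture(scope="session")
def ip3r_net():
    return ip3r_reference_network()


@pytest.fixture(scope="session")
def scenario_results():
    """All four packaged scenarios, simulated once per session."""
    return run_all_scenarios()
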