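import pytest

import calwave as cw


@pytest.fixture(scope="session")
def params() -> cw.ReactionParameters:
    return cw.ReactionParameters()


@pytest.fixture(scope="session")
def settings() -> cw.SimulationSettings:
    return cw.SimulationSettings()


@pytest.fixture(scope="session")
def chain_single(params, settings) -> cw.SimulationResult:
    """The reference run: 61-cell chain, middle cell stimulated."""
    return cw.run_chain_single(params, settings, 0.6)


@pytest.fixture(scope="session")
def chain_dual(params, settings) -> cw.SimulationResult:
    """Dual stimulation of the chain at cells 28 and 35 (labels 1 and 8)."""
    return cw.run_chain_dual(params, settings, 0.6)


@pytest.fixture(scope="session")
def sweep_settings() -> cw.SimulationSettings:
    """Coarser recording for sweep runs; classification only needs activation."""
    return cw.SimulationSettings(record_every=50)
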