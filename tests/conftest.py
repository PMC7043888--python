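import numpy as np
import pytest

import changedet as cd


@pytest.fixture(scope="session")
def task():
    return cd.TaskParams()


@pytest.fixture(scope="session")
def short_task():
    return cd.TaskParams(session_duration=600.0)


@pytest.fixture(scope="session")
def short_session(short_task):
    """One 10-min session with a moderate-performance agent."""
    return cd.simulate_session(short_task, cd.AgentParams(), seed=11)


@pytest.fixture(scope="session")
def familiar_vip_cells(short_session, short_task):
    """Per-cell summaries for a familiar-condition VIP population."""
    stim, _, _ = short_session
    pop = cd.PopulationParams(n_excitatory=0, n_vip=24, condition="familiar")
    traces = cd.generate_event_traces(stim, pop, seed=21)
    return traces, cd.summarize_cells(traces, stim, seed=22)


@pytest.fixture(scope="session")
def novel_vip_cells(short_session):
    stim, _, _ = short_session
    pop = cd.PopulationParams(n_excitatory=0, n_vip=24, condition="novel")
    traces = cd.generate_event_traces(stim, pop, seed=31)
    return traces, cd.summarize_cells(traces, stim, seed=32)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
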