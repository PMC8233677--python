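import numpy as np
import pytest

from opidyn import load_parameters
from opidyn.synthetic import toy_ledger_config


@pytest.fixture(scope="session")
def table1():
    """The packaged national point-estimate parameter set."""
    return load_parameters()


@pytest.fixture()
def toy():
    """Three-person toy population with hand-checkable round-number rates."""
    return load_parameters(toy_ledger_config())


def binomial_se(expected_events: float, population: float, n_agents: float) -> float:
    """Standard error of a scaled event count in an n-agent simulation.

    The per-agent event probability is the deterministic event total over
    the deterministic population; the scaled count is Binomial(n, q)
    times population / n.
    """
    q = expected_events / population
    scale = population / n_agents
    return float(np.sqrt(max(q * (1.0 - q), 1e-300) * n_agents) * scale)
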