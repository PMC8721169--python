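import numpy as np
import pytest

import hexnotch as hx


@pytest.fixture(scope="session")
def params():
    return hx.KineticParams()


@pytest.fixture
def zero_ranges():
    return {s: (0.0, 0.0) for s in hx.SPECIES}


@pytest.fixture(scope="session")
def lateral_inhibition_runs():
    """Five 20x20 cylindrical lateral-inhibition runs (shared, expensive)."""
    results = {}
    for seed in (1, 2, 3, 4, 5):
        cfg = hx.SimulationConfig(grid=hx.GridSpec(20, 20, "cylindrical"),
                                  rule=hx.LogicRule(dist=1, theta=1),
                                  seed=seed, t_max=300.0)
        results[seed] = hx.run(cfg)
    return results


def assert_states_close(a, b, rtol=1e-6, atol=1e-9):
    np.testing.assert_allclose(a, b, rtol=rtol, atol=atol)
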