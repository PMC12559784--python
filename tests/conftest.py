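import numpy as np
import pandas as pd
import pytest

import msfsgl as m


@pytest.fixture(scope="session")
def two_state_chart() -> m.StateChart:
    return m.StateChart(states=("alive", "dead"), transitions=((1, 2),))


@pytest.fixture(scope="session")
def toy_design(two_state_chart) -> m.StackedDesign:
    """Two subjects, one transition, covariate x = (1, 0), both fail."""
    df = pd.DataFrame({
        "id": [1, 2], "trans": [1, 1], "Tstart": [0.0, 0.0],
        "Tstop": [1.0, 2.0], "status": [1, 1], "x": [1.0, 0.0],
    })
    return m.expand_design(df, two_state_chart)


@pytest.fixture(scope="session")
def three_trans_chart() -> m.StateChart:
    return m.StateChart(
        states=("s1", "s2", "s3", "s4"),
        transitions=((1, 2), (1, 3), (1, 4)),
        similar_pairs=((1, 2),),
    )


@pytest.fixture(scope="session")
def aml_small():
    """Small simulated AML dataset shared across solver tests."""
    cfg = m.aml_dgp(N=200)
    rng = np.random.default_rng(11)
    data = m.simulate_paths(cfg, rng)
    design = m.expand_design(data, cfg.chart)
    ps = m.build_penalty_structure(cfg.chart, design.P)
    return cfg, data, design, ps
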