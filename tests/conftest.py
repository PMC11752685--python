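import numpy as np
import pytest

from cholmech import fixtures, pbtk


@pytest.fixture(scope="session")
def spec60():
    """Small synthetic study: 60 compounds, fixed seed."""
    return fixtures.FixtureSpec(n_compounds=60, seed=5)


@pytest.fixture(scope="session")
def table60(spec60):
    return fixtures.generate_compound_table(spec60)


@pytest.fixture(scope="session")
def oracle_panel(spec60):
    return fixtures.make_oracle_panel(spec60)


def random_parameter_sets(seed, n):
    """Randomized PBTK parameter sets: fub log-uniform in [0.01, 1], clint
    uniform in [0, 100]."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        fub = float(np.exp(rng.uniform(np.log(0.01), 0.0)))
        clint = float(rng.uniform(0.0, 100.0))
        out.append(pbtk.build_parameters(fub=fub, clint=clint))
    return out
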