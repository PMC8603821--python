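import numpy as np
import pytest

from ricehub.abm import CitySpec, EpiParams, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """Two small cities: fast runs for behavioural tests."""
    return SimulationConfig(
        cities=[
            CitySpec(name="Alpha", n_houses=30, humans_per_house=3, n_rmus=1),
            CitySpec(name="Beta", n_houses=30, humans_per_house=3, n_rmus=1),
        ],
        n_normal_days=30,
        n_covid_days=60,
    )


@pytest.fixture(scope="session")
def fixture_solutions():
    """Solved case-study scenarios, shared across tests."""
    from ricehub.fixtures import load_paper_fixture
    from ricehub.romodel import build_rc, solve

    out = {}
    for sc in (1, 2):
        uinst = load_paper_fixture(sc)
        out[sc] = (uinst, solve(build_rc(uinst)))
    return out
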