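from pathlib import Path

import pytest

from reflqc.merging import merge
from reflqc.simulate import SimulationConfig, simulate_dataset
from reflqc.symmetry import LAUE_MMM

DATA = Path(__file__).resolve().parents[1] / "src" / "reflqc" / "data"


@pytest.fixture(scope="session")
def raxis_header_text() -> str:
    return (DATA / "raxis_header.txt").read_text()


@pytest.fixture(scope="session")
def bruker_header_text() -> str:
    return (DATA / "bruker_header.txt").read_text()


@pytest.fixture(scope="session")
def standard_sim():
    """A mid-size clean simulation shared across statistics tests.

    ~7.5k unique reflections to 2.6 Å, redundancy 20, tau = 1, no ice.
    """
    cfg = SimulationConfig(d_min=2.6, seed=20)
    obs, truth = simulate_dataset(cfg)
    return cfg, obs, truth


@pytest.fixture(scope="session")
def standard_merged(standard_sim):
    _, obs, _ = standard_sim
    return merge(obs, LAUE_MMM)
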