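from pathlib import Path

import pytest
from hypothesis import settings

import receptorkit as rk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_table_path() -> Path:
    return DATA / "toy_proteins.tsv"


@pytest.fixture(scope="session")
def toy_design_path() -> Path:
    return DATA / "toy_design.tsv"


@pytest.fixture(scope="session")
def screen_table_path() -> Path:
    return DATA / "screen_scores.tsv"


@pytest.fixture(scope="session")
def toy_table(toy_table_path):
    return rk.read_protein_table(toy_table_path)


@pytest.fixture(scope="session")
def lfq_default():
    """Default synthetic pull-down dataset (2000 proteins, GST/bait 3v3)."""
    return rk.generate_lfq_dataset(rk.LfqSimConfig(seed=0))


@pytest.fixture(scope="session")
def toy_traj():
    """Default toy bound->unbound trajectory plus expected metric series."""
    return rk.generate_toy_trajectory(rk.TrajSimConfig(seed=0))
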