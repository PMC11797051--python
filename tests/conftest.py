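import numpy as np
import pandas as pd
import pytest

from ecoassembly.tables import CountTable
from ecoassembly.phylo import parse_newick, cophenetic
from ecoassembly.synthetic import ScenarioConfig, generate_experiment


def make_table(data: dict, taxa) -> CountTable:
    """Build a CountTable from {sample: [counts...]} aligned to taxa."""
    return CountTable(pd.DataFrame(data, index=list(taxa)))


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_tip_ladder():
    # ladder (caterpillar) tree: A,B are the closest pair
    return parse_newick("(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);")


@pytest.fixture
def six_tip_dm(six_tip_ladder):
    return cophenetic(six_tip_ladder)


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced neutral experiment reused by pipeline-level tests."""
    cfg = ScenarioConfig(
        n_taxa=60,
        process="neutral",
        flasks_per_group=1,
        gut_per_flask=2,
        read_depth=2000,
        guild_size=12,
        seed=11,
    )
    return cfg, generate_experiment(cfg)
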