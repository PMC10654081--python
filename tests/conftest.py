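import numpy as np
import pandas as pd
import pytest

from pitmud.phylo import parse_newick
from pitmud.synthetic import ScenarioConfig, simulate_tree
from pitmud.table import CommunityTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_counts(rng):
    """20 taxa x 12 samples random count table."""
    df = pd.DataFrame(rng.integers(0, 50, size=(20, 12)),
                      index=[f"O{i}" for i in range(20)],
                      columns=[f"s{i}" for i in range(12)])
    return CommunityTable(df)


@pytest.fixture
def balanced_tree4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def two_group_frame():
    ids = [f"s{i}" for i in range(12)]
    return pd.DataFrame({"g": ["A"] * 6 + ["B"] * 6}, index=ids)


@pytest.fixture(scope="session")
def bd_tree_30():
    return simulate_tree(ScenarioConfig(n_taxa=30, seed=3))


def random_tree(n_taxa: int, seed: int):
    """Small birth-death tree with relabelled tips (helper, not fixture)."""
    return simulate_tree(ScenarioConfig(n_taxa=n_taxa, seed=seed))


def sparse_table(taxa, n_samples: int, seed: int, density: float = 0.5):
    """Random sparse count table guaranteed nonempty per sample."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 30, (len(taxa), n_samples))
    counts = counts * (rng.random(counts.shape) < density)
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(0, len(taxa)), j] = 5
    return CommunityTable(pd.DataFrame(
        counts, index=list(taxa), columns=[f"s{j}" for j in range(n_samples)]))
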