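import numpy as np
import pandas as pd
import pytest

from phylobeta import CommunityTable, PhyloTree, scenario_fixture

#: printed worked-example values for the six presence-absence metrics on
#: the 16-tip unit-branch-length fixture, per scenario, at
#: lambda = 1, 0.75, 0.5, 0.25, 0.001 (in that order)
TABLE1 = {
    "dpw": {
        "A": [8, 8, 8, 8, 8],
        "B": [6, 6.5, 7, 7.5, 7.998],
        "C": [5.5, 6.125, 6.75, 7.375, 7.9975],
        "D": [4.5, 5.375, 6.25, 7.125, 7.9965],
    },
    "dnn": {
        "A": [8, 8, 8, 8, 8],
        "B": [6, 6.5, 7, 7.5, 7.998],
        "C": [2, 3.5, 5, 6.5, 7.994],
        "D": [2, 3.5, 5, 6.5, 7.994],
    },
    "phylosor": {
        "A": [0, 0, 0, 0, 2.22e-16],
        "B": [0.125, 0.075, 0.0417, 0.0179, 6.25e-05],
        "C": [0.6667, 0.4615, 0.2857, 0.1333, 0.0005],
        "D": [0.6364, 0.4286, 0.2593, 0.1186, 0.0004],
    },
    "unifrac": {
        "A": [1, 1, 1, 1, 1],
        "B": [0.9333, 0.9610, 0.9787, 0.9910, 0.9999],
        "C": [0.5, 0.7, 0.8333, 0.9286, 0.9997],
        "D": [0.5333, 0.7273, 0.8511, 0.9369, 0.9998],
    },
    "raod": {
        "A": [4, 4, 4, 4, 4],
        "B": [3, 3.25, 3.5, 3.75, 3.999],
        "C": [2.75, 3.0625, 3.375, 3.6875, 3.9988],
        "D": [2.25, 2.6875, 3.125, 3.5625, 3.9983],
    },
    "raoh": {
        "A": [2.75, 2.3125, 1.875, 1.4375, 1.0018],
        "B": [1.75, 1.5625, 1.375, 1.1875, 1.00078],
        "C": [0.25, 0.4375, 0.625, 0.8125, 0.9993],
        "D": [0.25, 0.4375, 0.625, 0.8125, 0.9993],
    },
}

LAMBDAS = (1.0, 0.75, 0.5, 0.25, 0.001)


@pytest.fixture(scope="session")
def fixture16():
    return scenario_fixture()


@pytest.fixture(scope="session")
def fixture16_table(fixture16):
    return fixture16.community_table()


@pytest.fixture()
def balanced4():
    return PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")


def star_tree(n_tips: int, depth: float = 1.0) -> PhyloTree:
    body = ",".join(f"t{i}:{depth}" for i in range(1, n_tips + 1))
    return PhyloTree.from_newick(f"({body});")


def random_community_pair(rng: np.random.Generator, species, allow_overlap=True):
    """Two non-empty random communities (presence lists + integer abundances)."""
    species = list(species)
    while True:
        m1 = rng.random(len(species)) < rng.uniform(0.2, 0.8)
        m2 = rng.random(len(species)) < rng.uniform(0.2, 0.8)
        if not allow_overlap:
            m2 &= ~m1
        if m1.any() and m2.any():
            break
    c1 = [s for s, m in zip(species, m1) if m]
    c2 = [s for s, m in zip(species, m2) if m]
    a1 = {s: int(rng.integers(1, 20)) for s in c1}
    a2 = {s: int(rng.integers(1, 20)) for s in c2}
    return c1, c2, a1, a2


def pair_to_table(species, c1, c2, a1=None, a2=None) -> CommunityTable:
    row1 = {s: (a1[s] if a1 else 1) if s in c1 else 0 for s in species}
    row2 = {s: (a2[s] if a2 else 1) if s in c2 else 0 for s in species}
    return CommunityTable(
        pd.DataFrame([row1, row2], index=["p1", "p2"], columns=list(species))
    )
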