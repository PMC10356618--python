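from __future__ import annotations

import numpy as np
import pytest

import phylorecruit as pr
from phylorecruit import simulate as sim
from phylorecruit.trees import SpeciesTree, TreeNode


@pytest.fixture
def cherry3():
    """((A:1,B:1):1,C:2); — the smallest interesting rooted tree."""
    return pr.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet():
    """((A,B),(C,D)) with unit branch lengths."""
    return pr.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def single_tip_tree():
    return SpeciesTree(TreeNode(label="A"))


@pytest.fixture(scope="session")
def standard_fixture():
    """The planted-recruitment study conditions: 9 tips, 5000 HOGs,
    10% root-planted recruitments, q_true = 0.3, fp rate 0.01, seed 11."""
    tree = sim.simulate_tree(9, seed=11)
    og, truth_og = sim.simulate_orthogroups(tree, n_hogs=5000, seed=12)
    stats, truth_reg = sim.simulate_regulation(
        tree, og, recruit_fraction=0.1, q_true=0.3, fp_deg_rate=0.01, seed=13
    )
    return {
        "tree": tree,
        "og": og,
        "stats": stats,
        "truth": truth_og.merged(truth_reg),
    }


@pytest.fixture(scope="session")
def small_dataset():
    """A small 6-tip dataset for fast integration tests."""
    tree = sim.simulate_tree(6, seed=5)
    og, truth = sim.simulate_orthogroups(tree, n_hogs=300, seed=6)
    stats, truth_reg = sim.simulate_regulation(tree, og, seed=7)
    return {"tree": tree, "og": og, "stats": stats, "truth": truth.merged(truth_reg)}


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
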