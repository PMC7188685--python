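import dendropy
import numpy as np
import pytest

from otomorph.phylo import TimeTree
from otomorph.simulate import SimulationSpec, simulate_shapes, simulate_tree


def make_timetree(newick: str, tip_ages=None) -> TimeTree:
    """TimeTree from a newick string with branch lengths; extant tips by default."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    if tip_ages is None:
        # infer from depths assuming the deepest tip is extant
        depths = {}
        for nd in tree.preorder_node_iter():
            depths[nd] = (
                0.0 if nd.parent_node is None
                else depths[nd.parent_node] + (nd.edge.length or 0.0)
            )
        mx = max(depths[l] for l in tree.leaf_node_iter())
        tip_ages = {l.taxon.label: mx - depths[l] for l in tree.leaf_node_iter()}
    return TimeTree(tree=tree, tip_ages=tip_ages)


@pytest.fixture(scope="session")
def small_timetree():
    """Ultrametric 4-tip balanced tree: ((A:1,B:1):1,(C:1,D:1):1);"""
    return make_timetree("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);")


@pytest.fixture(scope="session")
def sim_tree20():
    tt, occ = simulate_tree(20, seed=11)
    return tt, occ


@pytest.fixture(scope="session")
def sim_configs(sim_tree20):
    tt, _ = sim_tree20
    spec = SimulationSpec(n_taxa=20, seed=3)
    configs, labels = simulate_shapes(spec, tt)
    return configs, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
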