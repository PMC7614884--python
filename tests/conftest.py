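import numpy as np
import pytest

from ducttrace.tree import BranchingTree, DuctNode, LabelledCell, full_binary_tree


@pytest.fixture
def binary3():
    """Full binary tree of depth 3 (7 ducts, 4 terminals)."""
    return full_binary_tree(3)


@pytest.fixture
def binary4():
    return full_binary_tree(4)


@pytest.fixture
def rng():
    return np.random.default_rng(20230123)


def make_chain(n, length=10.0):
    """A linear chain of n ducts (no bifurcations)."""
    nodes = [DuctNode(id="n1", parent_id=None, level=1, length_um=length)]
    for i in range(2, n + 1):
        nodes.append(
            DuctNode(id=f"n{i}", parent_id=f"n{i-1}", level=i, length_um=length)
        )
    nodes[-1].has_acinus = True
    return BranchingTree(nodes)


def random_tree(rng, n_nodes=40, length=10.0):
    """Random rooted tree: each new node attaches to a uniformly chosen
    existing node."""
    nodes = {"n0": DuctNode(id="n0", parent_id=None, level=1, length_um=length)}
    ids = ["n0"]
    for i in range(1, n_nodes):
        parent = ids[rng.integers(len(ids))]
        nid = f"n{i}"
        nodes[nid] = DuctNode(
            id=nid,
            parent_id=parent,
            level=nodes[parent].level + 1,
            length_um=length,
        )
        ids.append(nid)
    return BranchingTree(nodes.values())


def cell(i, duct, color="RFP", compartment="luminal", in_acinus=False):
    return LabelledCell(
        id=f"c{i}", duct_id=duct, color=color, compartment=compartment, in_acinus=in_acinus
    )
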