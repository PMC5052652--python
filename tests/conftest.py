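import numpy as np
import pandas as pd
import pytest

from ornamass import trees as T
from ornamass.discrete import QMatrix
from ornamass.simulate import sim_bd_tree, sim_hansen, sim_mk


@pytest.fixture
def three_tip():
    return T.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_tree():
    return T.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def bd_tree():
    """Medium fossil birth-death tree shared across modules."""
    return sim_bd_tree(n_tips=40, birth=0.1, death=0.05, seed=101)


@pytest.fixture
def painted_tree(bd_tree):
    """True binary history and painting on the shared tree."""
    states, smap = sim_mk(bd_tree, QMatrix.binary(0.04, 0.04), root_state=0, seed=102)
    return states, smap


def random_tree(n, seed):
    return sim_bd_tree(n_tips=n, birth=0.1, death=0.04, seed=seed)


def enumerate_mk_loglik(tree, states, Q, root_freq):
    """Exhaustive sum over interior-node state assignments (oracle, <= 6 tips)."""
    from itertools import product

    from ornamass.discrete import transition_matrices

    nodes = list(tree.postorder())
    internal = [v for v in nodes if not v.is_tip]
    k = Q.matrix.shape[0]
    P = {id(v): transition_matrices(Q.matrix, np.array([v.length]))[0]
         for v in nodes if v.parent is not None}
    total = 0.0
    for assign in product(range(k), repeat=len(internal)):
        amap = {id(v): s for v, s in zip(internal, assign)}
        for v in nodes:
            if v.is_tip:
                amap[id(v)] = int(states[v.label])
        p = root_freq[amap[id(tree.root)]]
        for v in nodes:
            if v.parent is not None:
                p *= P[id(v)][amap[id(v.parent)], amap[id(v)]]
        total += p
    return np.log(total)
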