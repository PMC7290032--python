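"""Shared fixtures and the brute-force likelihood oracle.

The oracle enumerates every internal-node state assignment and sums the
path probabilities — independent of the pruning recursion it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm as scipy_expm

import phylocoev as pc
from phylocoev import synthetic_data as sd


@pytest.fixture
def three_tip_tree() -> pc.Phylogeny:
    return pc.parse_newick("((A:1,B:1):0.5,C:1.5);")


@pytest.fixture
def yule20() -> pc.Phylogeny:
    return sd.simulate_yule_tree(20, 1.0, seed=42)


def brute_force_loglik(phy, tip_states, gen, root_index=0) -> float:
    """Sum over all internal-node state assignments of path probabilities.

    Exponentially slow; usable only on tiny trees. Transition matrices
    come from scipy's expm so the oracle shares nothing with the
    package's pruning path.
    """
    k = gen.n_states
    Q = gen.Q()
    nodes = list(phy.tree.preorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    tips = [nd for nd in nodes if nd.is_leaf()]

    def tip_allowed(nd, state_idx):
        s = tip_states[nd.taxon.label]
        if gen.kind == "independent-single":
            return s is None or int(s) == (1, 0)[state_idx]
        g1, g2 = pc.cooccurrence.PAIR_STATES[state_idx]
        s1, s2 = s
        return (s1 is None or int(s1) == g1) and (s2 is None or int(s2) == g2)

    P = {}
    for nd in nodes:
        if nd.parent_node is not None:
            P[id(nd)] = scipy_expm(Q * (nd.edge.length or 0.0))

    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal) - 1):
        state = {id(internal[0]): root_index}
        for nd, s in zip(internal[1:], assign):
            state[id(nd)] = s
        prob = 1.0
        for nd in nodes:
            if nd.parent_node is None:
                continue
            ps = state[id(nd.parent_node)]
            if nd.is_leaf():
                prob *= sum(
                    P[id(nd)][ps, si] for si in range(k) if tip_allowed(nd, si)
                )
            else:
                prob *= P[id(nd)][ps, state[id(nd)]]
        total += prob
    if total <= 0:
        return -np.inf
    return float(np.log(total))


@pytest.fixture
def brute_oracle():
    return brute_force_loglik


def random_loss_tree(rng: np.random.Generator, n_tips: int) -> pc.Phylogeny:
    """Random small tree with exponential branch lengths for oracle checks."""
    return sd.simulate_yule_tree(n_tips, 1.0, seed=int(rng.integers(2**31)))
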