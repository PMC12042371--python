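import numpy as np
import pytest

from biogeofit.chronogram import parse_newick
from biogeofit.rangespace import Geography, GeoRange, build_state_space


@pytest.fixture(scope="session")
def space2():
    return build_state_space(["A", "B"], 2)


@pytest.fixture(scope="session")
def space3():
    return build_state_space(["A", "B", "C"], 2)


@pytest.fixture(scope="session")
def tree4():
    """Balanced 4-tip ultrametric tree of depth 2.5 my."""
    return parse_newick("((t1:1,t2:1):1.5,(t3:2.5,t4:2.5):0.0):0;")


@pytest.fixture(scope="session")
def geo4_2areas(space2):
    return Geography(
        space2,
        {
            "t1": GeoRange(0b01),
            "t2": GeoRange(0b10),
            "t3": GeoRange(0b11),
            "t4": GeoRange(0b01),
        },
    )


def brute_force_reference(tree, geo, spec, params, space, multipliers=None):
    """Exhaustive-enumeration likelihood and node marginals.

    Sums the joint probability over every assignment of a range state to
    every internal node (the state entering that node's cladogenesis),
    marginalizing the per-branch anagenetic transitions analytically via
    the transition matrix.  Independent of the pruning implementation;
    only feasible for tiny trees and state spaces.
    """
    import itertools
    import math

    from biogeofit.decmodels import (
        build_rate_matrix,
        cladogenesis_table,
        transition_matrix,
    )

    S = space.n_states
    if multipliers is None:
        multipliers = np.ones((space.n_areas, space.n_areas))
    Q = build_rate_matrix(space, params, multipliers)
    ct = cladogenesis_table(space, spec, params.j if spec.with_j else 0.0)
    C = np.zeros((S, S, S))
    for a, l, r, p in zip(ct.anc_idx, ct.left_idx, ct.right_idx, ct.prob):
        C[a, l, r] += p
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip]
    idx = {id(n): i for i, n in enumerate(internals)}
    tip_state = {n.label: space.index_of(geo[n.label]) for n in nodes if n.is_tip}
    pi = np.full(S, 1.0 / (S - 1))
    pi[0] = 0.0
    pcache = {}

    def P(t):
        if t not in pcache:
            pcache[t] = transition_matrix(Q, t)
        return pcache[t]

    total = 0.0
    marginals = {id(n): np.zeros(S) for n in internals}
    for assign in itertools.product(range(S), repeat=len(internals)):
        prob = pi[assign[idx[id(tree.root)]]]
        if prob == 0:
            continue
        for n in internals:
            a = assign[idx[id(n)]]
            msgs = []
            for c in n.children:
                bottom = tip_state[c.label] if c.is_tip else assign[idx[id(c)]]
                msgs.append(P(n.age - c.age)[:, bottom])
            prob *= float(np.einsum("lr,l,r", C[a], msgs[0], msgs[1]))
            if prob == 0:
                break
        if prob == 0:
            continue
        total += prob
        for n in internals:
            marginals[id(n)][assign[idx[id(n)]]] += prob
    for k in marginals:
        marginals[k] /= total
    return math.log(total), marginals
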