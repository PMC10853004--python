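"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own algorithms: likelihoods
and posteriors by exhaustive enumeration over internal-node states,
accessibility by direct permutation checking, epistatic coefficients by
combinatorial inclusion–exclusion.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epistascape.asr import _node_name, load_tree
from epistascape.genotype import MutationSite
from epistascape.simulate import samt_preset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset():
    """The default four-site methyltransferase landscape preset."""
    return samt_preset()


@pytest.fixture(scope="session")
def four_sites(preset):
    return preset[0]


@pytest.fixture()
def two_sites():
    return [MutationSite.from_label("Y267Q"), MutationSite.from_label("M329L")]


# ---------------------------------------------------------------------------
# oracles


def brute_force_accessibility(values: dict, sites, epsilon: float = 0.0):
    """Check every permutation of sites directly for monotonicity."""
    labels = [s.label for s in sites]
    out = {}
    for perm in itertools.permutations(labels):
        acquired = set()
        current = values["0" * len(labels)]
        ok = True
        for step in perm:
            acquired.add(step)
            nxt = values["".join("1" if l in acquired else "0" for l in labels)]
            if nxt < current - epsilon:
                ok = False
                break
            current = nxt
        out[perm] = ok
    return out


def inclusion_exclusion_coefficients(values: dict, labels):
    """Reference-coded epistatic coefficients computed combinatorially.

    beta_T = sum over subsets S of T of (-1)^(|T|-|S|) * y(genotype with S
    mutated); with 0/1 coding and a saturated model these are the OLS
    coefficients.
    """
    n = len(labels)
    coeffs = {}
    for size in range(n + 1):
        for T in itertools.combinations(range(n), size):
            beta = 0.0
            for r in range(size + 1):
                for S in itertools.combinations(T, r):
                    g = "".join("1" if i in S else "0" for i in range(n))
                    beta += (-1) ** (size - r) * values[g]
            coeffs[tuple(labels[i] for i in T)] = beta
    return coeffs


def enumeration_likelihood_and_posteriors(tree, seqs: dict, model, site: int):
    """Site likelihood and internal-node posteriors by brute-force summation
    over every assignment of states to internal nodes."""
    t = load_tree(tree)
    nodes = list(t.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    k = model.n_states
    idx = {a: i for i, a in enumerate(model.alphabet)}
    total = 0.0
    post = {id(n): np.zeros(k) for n in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        p = model.freqs[amap[id(t.seed_node)]]
        for n in nodes:
            if n is t.seed_node:
                continue
            P = model.transition_matrix(n.edge.length or 0.0)
            if n.is_leaf():
                c = seqs[_node_name(n)][site]
                if c in idx:
                    p *= P[amap[id(n.parent_node)], idx[c]]
            else:
                p *= P[amap[id(n.parent_node)], amap[id(n)]]
        total += p
        for n in internals:
            post[id(n)][amap[id(n)]] += p
    posteriors = {
        _node_name(n): post[id(n)] / total for n in internals if _node_name(n)
    }
    return total, posteriors


def random_binary_newick(leaf_names, rng, name_internal=False) -> str:
    """A random rooted binary tree over the given leaves with uniform(0.05,
    0.5) branch lengths, built by repeated random joins."""
    nodes = [(name, None) for name in leaf_names]
    counter = itertools.count(1)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (a, _), (b, _) = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 0.5, size=2)
        label = f"N{next(counter)}" if name_internal else ""
        merged = f"({a}:{la:.4f},{b}:{lb:.4f}){label}"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append((merged, None))
    return nodes[0][0] + ";"


def brute_force_fitch(tree, leaf_states: dict) -> int:
    """Minimum change count by enumerating all internal-node labelings."""
    t = load_tree(tree)
    nodes = list(t.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    alphabet = sorted(set(leaf_states.values()))
    best = None
    for assign in itertools.product(alphabet, repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        for n in nodes:
            if n.is_leaf():
                amap[id(n)] = leaf_states[_node_name(n)]
        changes = sum(
            amap[id(n)] != amap[id(n.parent_node)]
            for n in nodes
            if n.parent_node is not None
        )
        best = changes if best is None else min(best, changes)
    return best
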