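"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from lichenscan.tree import PhyloTree, parse_newick


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:1);")


def random_tree(rng: np.random.Generator, n_tips: int, max_len: float = 1.5) -> PhyloTree:
    """Random binary topology with exponential-ish branch lengths (test helper)."""
    parent = [-1]
    lengths = [0.0]
    labels: list[str | None] = [None]
    leaves = [0]
    while len(leaves) < n_tips:
        v = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            parent.append(v)
            lengths.append(float(rng.uniform(0.05, max_len)))
            labels.append(None)
            leaves.append(len(parent) - 1)
    for i, v in enumerate(sorted(leaves)):
        labels[v] = f"t{i}"
    return PhyloTree(parent, lengths, labels, 0)


def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form 2-state transition matrix, written independently of the
    package implementation."""
    s = q01 + q10
    e = math.exp(-s * t)
    return np.array(
        [
            [(q10 + q01 * e) / s, (q01 - q01 * e) / s],
            [(q10 - q10 * e) / s, (q01 + q10 * e) / s],
        ]
    )


def enumeration_loglik(tree: PhyloTree, trait: dict[str, int], q01, q10, prior) -> float:
    """Brute-force likelihood: sum over every ancestral-state assignment."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tip_states = {i: trait[tree.labels[i]] for i in tree.tip_indices()}
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = dict(zip(internal, assign))
        states.update(tip_states)
        p = prior[states[tree.root]]
        for v in range(tree.n_nodes):
            par = tree.parent[v]
            if par >= 0:
                p *= transition_matrix(q01, q10, tree.lengths[v])[states[par], states[v]]
        total += p
    return math.log(total)


def enumeration_posterior(tree, trait, q01, q10, prior, node) -> float:
    """Brute-force marginal posterior P(state=1 at node)."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tip_states = {i: trait[tree.labels[i]] for i in tree.tip_indices()}
    num = den = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = dict(zip(internal, assign))
        states.update(tip_states)
        p = prior[states[tree.root]]
        for v in range(tree.n_nodes):
            par = tree.parent[v]
            if par >= 0:
                p *= transition_matrix(q01, q10, tree.lengths[v])[states[par], states[v]]
        den += p
        if states[node] == 1:
            num += p
    return num / den
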