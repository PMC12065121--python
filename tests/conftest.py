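"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from cladesignal.tree import Node, PhyloTree, parse_newick


def random_tree(rng: np.random.Generator, n_leaves: int,
                polytomy_prob: float = 0.25) -> PhyloTree:
    """Random rooted tree, optionally with polytomies, labelled L0..Ln."""
    nodes = [Node(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        k = 2
        if len(nodes) >= 3 and rng.random() < polytomy_prob:
            k = 3
        picks = sorted(rng.choice(len(nodes), size=k, replace=False))
        joined = Node()
        for i in picks:
            joined.add_child(nodes[i])
        for i in reversed(picks):
            del nodes[i]
        nodes.append(joined)
    root = nodes[0]
    if root.is_terminal:  # n_leaves == 1
        wrap = Node()
        wrap.add_child(root)
        root = wrap
    return PhyloTree(root)


def brute_force_parsimony(tree: PhyloTree, column: pd.Series,
                          alphabet: tuple[str, ...]) -> int:
    """Exhaustive minimization over all internal-node labelings.

    Wildcard leaves contribute zero cost for any parental state, so only
    internal nodes need enumeration.  Independent of the package's
    Hartigan/Sankoff code paths.
    """
    internal = [n for n in tree.root.preorder() if not n.is_terminal]
    leaves = [n for n in tree.root.preorder() if n.is_terminal]
    allowed = {
        leaf: (set(alphabet) if column[leaf.name] in ("?", "NA")
               else {column[leaf.name]})
        for leaf in leaves
    }
    best = None
    for assignment in itertools.product(alphabet, repeat=len(internal)):
        states = dict(zip(internal, assignment))
        cost = 0
        for node in internal:
            if node.parent is not None and states[node.parent] != states[node]:
                cost += 1
        for leaf in leaves:
            if states[leaf.parent] not in allowed[leaf]:
                cost += 1
        if best is None or cost < best:
            best = cost
    return best


def random_character(rng: np.random.Generator, tree: PhyloTree,
                     n_states: int, wildcard_prob: float = 0.15) -> pd.Series:
    states = [str(i) for i in range(n_states)]
    values = {}
    for label in sorted(tree.terminal_labels):
        if rng.random() < wildcard_prob:
            values[label] = "?"
        else:
            values[label] = states[rng.integers(n_states)]
    # guarantee at least one observed state
    if all(v == "?" for v in values.values()):
        first = sorted(values)[0]
        values[first] = states[0]
    return pd.Series(values, name="char")


@pytest.fixture
def quartet():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def ladder():
    return parse_newick("(((A,B),C),D);")
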