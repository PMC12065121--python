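"""Synthetic trees, clade partitions and metadata with planted signal.

The generator emulates the statistical shape of a curated host/parasite
dataset: a rooted tree whose terminals fall into k disjoint monophyletic
clades, a categorical metadata table whose host-taxonomy columns nest
hierarchically (class > order > family > genus > species) and whose
geography columns nest country under continent, and a tunable dependence
between clade and metadata.  Each clade owns a characteristic profile
(one designated value per feature group); a terminal draws its values
from the clade profile with probability ``signal`` and from the global
value pool with probability ``1 - signal``.  Missing cells and
paratenic/intermediate-host rows (which curation must discard) are
injected at configurable rates.

Defaults mirror the study scale this package targets: 8 clades over 494
terminals, ten features with cardinalities (5, 28, 63, 116, 170, 2, 3,
10, 7, 42), signal 0.9.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .parsimony import CharacterMatrix, MISSING
from .preprocess import ROLE_COLUMN
from .tree import Clade, CladePartition, Node, PhyloTree


@dataclass(frozen=True)
class FeatureSpec:
    """One categorical feature: its cardinality and optional parent."""

    name: str
    cardinality: int
    parent: str | None = None


#: Ten-feature schema at the cardinalities of the target study.
DEFAULT_SCHEMA: tuple[FeatureSpec, ...] = (
    FeatureSpec("CatHC", 5),
    FeatureSpec("CatHO", 28, parent="CatHC"),
    FeatureSpec("CatHF", 63, parent="CatHO"),
    FeatureSpec("CatHG", 116, parent="CatHF"),
    FeatureSpec("CatHS", 170, parent="CatHG"),
    FeatureSpec("CatE1", 2),
    FeatureSpec("CatE2", 3),
    FeatureSpec("CatL1", 10),
    FeatureSpec("CatL2", 7),
    FeatureSpec("CatL5", 42, parent="CatL2"),
)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the study-scale conditions."""

    n_clades: int = 8
    n_terminals: int = 494
    clade_sizes: tuple[int, ...] | None = None
    schema: tuple[FeatureSpec, ...] = DEFAULT_SCHEMA
    signal: float = 0.9
    missing_rate: float = 0.0
    paratenic_rate: float = 0.0
    disjoint_profiles: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.clade_sizes is None:
            base, extra = divmod(self.n_terminals, self.n_clades)
            self.clade_sizes = tuple(
                base + (1 if i < extra else 0) for i in range(self.n_clades)
            )
        else:
            self.clade_sizes = tuple(int(s) for s in self.clade_sizes)
            self.n_clades = len(self.clade_sizes)
            self.n_terminals = sum(self.clade_sizes)
        if self.n_clades < 2:
            raise ValidationError("need at least two clades")
        if any(s < 1 for s in self.clade_sizes):
            raise ValidationError("clade sizes must be positive")
        if not 0 <= self.signal <= 1:
            raise ValidationError("signal must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing rate must lie in [0, 1)")
        if not 0 <= self.paratenic_rate < 1:
            raise ValidationError("paratenic rate must lie in [0, 1)")
        names = [f.name for f in self.schema]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names in schema")
        for f in self.schema:
            if f.parent is not None and f.parent not in names:
                raise ValidationError(
                    f"feature {f.name!r} nests under unknown {f.parent!r}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {f.name: f.parent for f in self.schema}
        for name in parents:
            seen = set()
            cur = name
            while cur is not None:
                if cur in seen:
                    raise ValidationError("cyclic feature nesting")
                seen.add(cur)
                cur = parents[cur]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), stream])
    )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _coalesce(nodes: list[Node], rng: np.random.Generator) -> Node:
    """Random sequence of pairwise joins; returns the resulting root."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = Node()
        joined.add_child(nodes[i])
        joined.add_child(nodes[j])
        nodes[j] = joined
        del nodes[i]
    return nodes[0]


def make_tree_with_clades(
    config: SyntheticConfig,
) -> tuple[PhyloTree, CladePartition]:
    """Random rooted binary tree with k planted monophyletic clades.

    Terminals coalesce randomly within each clade, then the clade roots
    coalesce among themselves, so every clade's terminal set equals a
    node's subtree by construction.
    """
    rng = _rng(config, 0)
    clades: dict[str, Clade] = {}
    roots: list[Node] = []
    counter = 1
    for ci, size in enumerate(config.clade_sizes):
        names = [f"t{counter + i:04d}" for i in range(size)]
        counter += size
        leaves = [Node(name=n) for n in names]
        roots.append(_coalesce(leaves, rng) if size > 1 else leaves[0])
        clades[f"Clade_{ci + 1}"] = Clade(
            f"Clade_{ci + 1}", frozenset(names)
        )
    root = _coalesce(roots, rng)
    if root.is_terminal:  # k=1 guarded earlier; defensive
        raise ValidationError("degenerate tree")
    return PhyloTree(root), CladePartition(clades)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def _build_hierarchy(
    schema: Sequence[FeatureSpec],
) -> tuple[dict[str, list[str]], dict[str, dict[str, str]], list[list[str]]]:
    """Value pools, child-value -> parent-value maps, and feature chains.

    Each chain is ordered leaf-first (species before genus...); a chain of
    length one is an independent feature.
    """
    values = {
        f.name: [f"{f.name}_v{i + 1:03d}" for i in range(f.cardinality)]
        for f in schema
    }
    specs = {f.name: f for f in schema}
    parent_map: dict[str, dict[str, str]] = {}
    for f in schema:
        if f.parent is None:
            continue
        n_parent = specs[f.parent].cardinality
        # round-robin keeps every parent category populated
        parent_map[f.name] = {
            v: values[f.parent][i % n_parent]
            for i, v in enumerate(values[f.name])
        }
    children = {f.parent for f in schema if f.parent is not None}
    chains = []
    for f in schema:
        if f.name in children:
            continue  # not a chain leaf
        chain = [f.name]
        cur = f.parent
        while cur is not None:
            chain.append(cur)
            cur = specs[cur].parent
        chains.append(chain)
    return values, parent_map, chains


def _profile_leaves(
    chains: list[list[str]],
    values: Mapping[str, list[str]],
    k: int,
    rng: np.random.Generator,
    disjoint: bool,
) -> dict[str, list[str]]:
    """Designated leaf value per clade for every chain-leaf feature."""
    profiles = {}
    for chain in chains:
        leaf = chain[0]
        pool = values[leaf]
        if len(pool) >= k:
            profiles[leaf] = list(rng.choice(pool, size=k, replace=False))
        else:
            profiles[leaf] = list(rng.choice(pool, size=k, replace=True))
    if disjoint and all(len(values[c[0]]) < k for c in chains):
        raise ValidationError(
            "no feature has enough categories for disjoint clade profiles"
        )
    return profiles


def make_metadata(
    partition: CladePartition, config: SyntheticConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Clade-correlated metadata table and terminal -> clade labels.

    Per terminal and per feature chain, the chain-leaf value is the clade
    profile with probability ``signal`` and a uniform draw from the global
    pool otherwise; ancestor values follow the declared nesting, so every
    generated row is hierarchy-consistent.  Missing cells are injected at
    ``missing_rate`` and a ``paratenic_rate`` fraction of rows is flagged
    as intermediate/paratenic-host records.
    """
    rng = _rng(config, 1)
    values, parent_map, chains = _build_hierarchy(config.schema)
    clade_names = [name for name, _ in partition]
    profiles = _profile_leaves(
        chains, values, len(clade_names), rng, config.disjoint_profiles
    )
    clade_index = {name: i for i, name in enumerate(clade_names)}
    labels: dict[str, str] = {}
    for name, clade in partition:
        for term in clade.terminals:
            labels[term] = name

    terminals = sorted(labels)
    feature_order = [f.name for f in config.schema]
    rows = {}
    for term in terminals:
        ci = clade_index[labels[term]]
        row: dict[str, str] = {}
        for chain in chains:
            leaf = chain[0]
            if rng.random() < config.signal:
                value = profiles[leaf][ci]
            else:
                value = values[leaf][rng.integers(len(values[leaf]))]
            row[leaf] = value
            for feat in chain[1:]:
                value = parent_map[chain[chain.index(feat) - 1]][value]
                row[feat] = value
        rows[term] = [row[f] for f in feature_order]

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=feature_order
    )
    table.index.name = "terminal"

    if config.missing_rate > 0:
        mask = rng.random(table.shape) < config.missing_rate
        table = table.mask(pd.DataFrame(mask, index=table.index,
                                        columns=table.columns))

    roles = np.array(["definitive"] * len(table), dtype=object)
    n_flag = int(round(config.paratenic_rate * len(table)))
    if n_flag:
        flagged = rng.choice(len(table), size=n_flag, replace=False)
        for j, i in enumerate(flagged):
            roles[i] = "paratenic" if j % 2 == 0 else "intermediate"
    table[ROLE_COLUMN] = roles
    return table, labels


# ---------------------------------------------------------------------------
# Character matrices with planted changes
# ---------------------------------------------------------------------------


def plant_character(
    tree: PhyloTree,
    placements: Sequence[tuple[frozenset[str] | set[str], str]],
    ancestral: str = "s0",
    name: str = "char",
) -> pd.Series:
    """Terminal states implied by placing state changes on given branches.

    ``placements`` pairs a branch (identified by its subtended terminal
    set) with the derived state acquired there.  Nested placements are
    applied outermost-first, so deeper branches override shallower ones.
    """
    node_sets = {n.terminal_set() for n in tree.root.preorder()}
    states = {t: ancestral for t in tree.terminal_labels}
    ordered = sorted(placements, key=lambda p: -len(p[0]))
    for branch, state in ordered:
        branch = frozenset(branch)
        if branch not in node_sets:
            raise ValidationError(
                f"placement {sorted(branch)[:3]}... is not a branch of the tree"
            )
        for t in branch:
            states[t] = state
    return pd.Series(states, name=name).sort_index()


def make_character_matrix(
    tree: PhyloTree,
    n_chars: int,
    config: SyntheticConfig | None = None,
    *,
    n_changes: int = 1,
    seed: int | None = None,
    clean: bool = True,
) -> tuple[CharacterMatrix, list[dict]]:
    """Characters evolved by planting a known number of changes.

    With ``clean=True`` the chosen branches are pairwise disjoint and the
    derived states distinct, so the planted change count equals the true
    minimum and hence the parsimony score.  Returns the matrix plus, per
    character, a record of the planted branches, states and count.
    """
    if seed is None:
        seed = config.seed if config is not None else 0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    internal = [n.terminal_set() for n in tree.internal_nodes()]
    if n_changes > len(internal):
        raise ValidationError(
            f"cannot place {n_changes} changes on {len(internal)} internal "
            "branches"
        )
    columns = {}
    truth = []
    for ci in range(n_chars):
        order = list(rng.permutation(len(internal)))
        chosen: list[frozenset[str]] = []
        for idx in order:
            if len(chosen) == n_changes:
                break
            cand = internal[idx]
            if clean and any(cand & c for c in chosen):
                continue
            chosen.append(cand)
        if len(chosen) < n_changes:
            raise ValidationError(
                "not enough disjoint branches for the requested changes"
            )
        placements = [
            (branch, f"s{j + 1}" if clean else "s1")
            for j, branch in enumerate(chosen)
        ]
        name = f"char{ci + 1}"
        columns[name] = plant_character(tree, placements, name=name)
        truth.append(
            {
                "character": name,
                "planted_changes": len(chosen),
                "branches": chosen,
                "states": [s for _, s in placements],
            }
        )
    data = pd.DataFrame(columns)
    return CharacterMatrix(data), truth
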