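"""Rooted phylogenetic trees: parsing, clade extraction and comparison.

Trees are rooted, polytomies are first-class, and a *clade* is the full
terminal set of a non-root internal node (rooted-tree semantics: no
bipartition complementation).  Newick parsing is delegated to dendropy,
which handles quoted labels and bracket comments; the parsed topology is
converted into a light in-package node structure that the parsimony and
simulation code manipulates directly.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import dendropy

from .errors import NewickParseError, ValidationError

#: Label used for terminals that belong to no clade of a partition.
UNASSIGNED = "UNASSIGNED"


class Node:
    """One node of a rooted tree (terminal iff it has no children)."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None):
        self.name: str | None = name
        self.length: float | None = length
        self.support: float | None = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_terminal(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def terminal_set(self) -> frozenset[str]:
        return frozenset(n.name for n in self.preorder() if n.is_terminal)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_terminal:
            return f"Node({self.name!r})"
        return f"Node(<{len(self.children)} children>)"


class PhyloTree:
    """A validated rooted tree with uniquely labelled terminals."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.preorder():
            if node.is_terminal:
                if not node.name:
                    raise ValidationError("terminal with empty label")
                if node.name in seen:
                    raise ValidationError(
                        f"duplicate terminal label: {node.name!r}"
                    )
                seen.add(node.name)
            elif len(node.children) < 2 and node is not self.root:
                raise ValidationError("internal node with a single child")
        if self.root.is_terminal:
            raise ValidationError("tree must have at least one internal node")
        self._terminals: dict[str, Node] = {
            n.name: n for n in self.root.preorder() if n.is_terminal
        }

    # -- queries -----------------------------------------------------------

    @property
    def terminal_labels(self) -> frozenset[str]:
        return frozenset(self._terminals)

    def terminal(self, label: str) -> Node:
        return self._terminals[label]

    def internal_nodes(self, include_root: bool = False) -> list[Node]:
        return [
            n
            for n in self.root.preorder()
            if not n.is_terminal and (include_root or n is not self.root)
        ]

    def clade_sets(self) -> set[frozenset[str]]:
        """Terminal sets of all non-root internal nodes."""
        return {n.terminal_set() for n in self.internal_nodes()}

    def copy(self) -> "PhyloTree":
        def _clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return PhyloTree(_clone(self.root))

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt_label(name: str) -> str:
            if re.search(r"[\s,;:()\[\]']", name):
                return "'" + name.replace("'", "''") + "'"
            return name

        def fmt(node: Node) -> str:
            if node.is_terminal:
                out = fmt_label(node.name)
            else:
                out = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.support is not None:
                    out += format(node.support, "g")
                elif node.name:
                    out += fmt_label(node.name)
            if node.length is not None:
                out += ":" + format(node.length, "g")
            return out

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self._terminals)} terminals)"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name, length=dnode.edge.length)
        else:
            support = None
            name = dnode.label
            if name is not None:
                try:
                    support = float(name)
                    name = None
                except ValueError:
                    pass
            node = Node(name=name, length=dnode.edge.length, support=support)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        return node

    dtree.suppress_unifurcations()
    return PhyloTree(convert(dtree.seed_node))


def parse_newick(text: str) -> PhyloTree:
    """Parse one rooted tree from a Newick string.

    Internal node labels that parse as numbers are interpreted as support
    values; square-bracket comments are ignored; single-quoted labels are
    honoured.  Duplicate terminal labels raise :class:`ValidationError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        label = re.search(r"'([^']+)'", str(exc))
        raise ValidationError(
            "duplicate terminal label"
            + (f": {label.group(1)!r}" if label else f" ({exc})")
        ) from exc
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter() if leaf.taxon]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValidationError(
            f"duplicate terminal label: {sorted(dupes)[0]!r}"
        )
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Clades and partitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Clade:
    """A named set of terminal labels (a monophyletic group when bound)."""

    identifier: str
    terminals: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.terminals:
            raise ValidationError(f"clade {self.identifier!r} is empty")

    def __len__(self) -> int:
        return len(self.terminals)


class CladePartition:
    """Named, pairwise-disjoint terminal sets — the prediction labels."""

    def __init__(self, clades: Mapping[str, Clade] | Mapping[str, set]):
        self.clades: dict[str, Clade] = {}
        seen: dict[str, str] = {}
        for name, clade in clades.items():
            if not isinstance(clade, Clade):
                clade = Clade(name, frozenset(clade))
            for term in clade.terminals:
                if term in seen:
                    raise ValidationError(
                        f"terminal {term!r} assigned to both "
                        f"{seen[term]!r} and {name!r}"
                    )
                seen[term] = name
            self.clades[name] = clade

    def __iter__(self):
        return iter(self.clades.items())

    def __len__(self):
        return len(self.clades)

    def __getitem__(self, name: str) -> Clade:
        return self.clades[name]

    @property
    def terminals(self) -> frozenset[str]:
        return frozenset().union(*(c.terminals for c in self.clades.values()))

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            name: sorted(clade.terminals) for name, clade in self.clades.items()
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CladePartition":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    payload = json.load(fh)
        return cls({name: frozenset(terms) for name, terms in payload.items()})

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["terminal", "clade"])
            for name, clade in self.clades.items():
                for term in sorted(clade.terminals):
                    writer.writerow([term, name])

    @classmethod
    def from_csv(cls, path) -> "CladePartition":
        groups: dict[str, set[str]] = {}
        if hasattr(path, "read"):
            fh = path
            rows = csv.DictReader(fh)
            for row in rows:
                groups.setdefault(row["clade"], set()).add(row["terminal"])
        else:
            with open(path, newline="", encoding="utf-8") as fh:
                for row in csv.DictReader(fh):
                    groups.setdefault(row["clade"], set()).add(row["terminal"])
        return cls(groups)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def extract_clades(tree: PhyloTree, min_size: int) -> list[Clade]:
    """All clades (non-root internal nodes) with at least ``min_size`` terminals.

    Ordered by decreasing size, then by the lexicographically smallest
    member label.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    clades = []
    for node in tree.internal_nodes():
        terms = node.terminal_set()
        if len(terms) >= min_size:
            clades.append(terms)
    clades.sort(key=lambda s: (-len(s), min(s)))
    return [
        Clade(identifier=f"clade_{i + 1}", terminals=s)
        for i, s in enumerate(clades)
    ]


def compare_clade_sets(
    tree_a: PhyloTree, tree_b: PhyloTree
) -> tuple[int, int, int]:
    """Count clades shared between two rooted trees on the same terminals.

    Returns ``(shared, only_a, only_b)`` where a clade is the terminal set
    of a non-root internal node.
    """
    if tree_a.terminal_labels != tree_b.terminal_labels:
        diff = tree_a.terminal_labels ^ tree_b.terminal_labels
        raise ValidationError(
            f"trees are defined on different terminals; symmetric "
            f"difference: {sorted(diff)}"
        )
    set_a = tree_a.clade_sets()
    set_b = tree_b.clade_sets()
    shared = len(set_a & set_b)
    return shared, len(set_a) - shared, len(set_b) - shared


def label_terminals(
    tree: PhyloTree, partition: CladePartition
) -> dict[str, str]:
    """Map every tree terminal to its clade name, or :data:`UNASSIGNED`.

    Monophyly of each clade on the tree is verified; violations produce a
    warning (the labels are still returned).
    """
    unknown = partition.terminals - tree.terminal_labels
    if unknown:
        raise ValidationError(
            f"partition terminals absent from tree: {sorted(unknown)}"
        )
    node_sets = tree.clade_sets() | {
        frozenset([t]) for t in tree.terminal_labels
    }
    labels = {term: UNASSIGNED for term in tree.terminal_labels}
    for name, clade in partition:
        if clade.terminals not in node_sets:
            warnings.warn(
                f"clade {name!r} is not monophyletic on the tree",
                stacklevel=2,
            )
        for term in clade.terminals:
            labels[term] = name
    return labels
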