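"""Parsimony optimization of categorical characters on rooted trees.

Implements unordered (Fitch-style) parsimony generalized to hard
polytomies, ACCTRAN/DELTRAN most-parsimonious reconstructions, and the
classification of nonambiguous state transformations as *unique*
(synapomorphic, derived state exclusive to the clade and arising once),
*private* (homoplastic but exclusive to the clade) or *nonprivate*
(homoplastic with bearers outside the clade).  Branches carrying no
nonambiguous transformation of any character can be collapsed, which on
weakly structured data yields the highly polytomic cladograms typical of
host/biogeography characters.

Missing ("?") and inapplicable ("NA") cells are optimized as wildcards
over the character's full alphabet: they can adopt any state for free and
therefore never create transformation events on their own.

The polytomy downpass is Hartigan's generalization of Fitch's algorithm:
at each internal node, states are scored by how many child state-sets
contain them; the node keeps the maximally covered states and pays one
step per uncovered child.  ACCTRAN/DELTRAN reconstructions are obtained
from a unit-cost dynamic program (minimum total changes per rooted state,
computed bottom-up) followed by a top-down pass that, at branches where
keeping or changing the state are both optimal, changes as early as
possible (ACCTRAN) or keeps the parental state (DELTRAN).  Remaining ties
are broken by the character's declared alphabet order, making both
reconstructions deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .tree import Node, PhyloTree

#: Cell values treated as full-alphabet wildcards during optimization.
MISSING = "?"
INAPPLICABLE = "NA"
WILDCARDS = frozenset({MISSING, INAPPLICABLE})


class CharacterMatrix:
    """Terminals x categorical characters, with per-character alphabets.

    Parameters
    ----------
    data
        DataFrame indexed by terminal label, one column per character.
        Cells hold state codes as strings, ``"?"`` for missing or ``"NA"``
        for inapplicable.
    alphabets
        Optional mapping character -> ordered state alphabet.  By default
        the alphabet is the sorted set of observed non-wildcard states.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        alphabets: Mapping[str, Sequence[str]] | None = None,
    ):
        if data.index.has_duplicates:
            raise ValidationError("duplicate terminal labels in matrix")
        self.data = data.astype(str)
        self.alphabets: dict[str, tuple[str, ...]] = {}
        for char in self.data.columns:
            observed = [
                v for v in self.data[char] if v not in WILDCARDS
            ]
            if alphabets is not None and char in alphabets:
                alpha = tuple(alphabets[char])
                bad = set(observed) - set(alpha)
                if bad:
                    raise ValidationError(
                        f"character {char!r}: states {sorted(bad)} outside "
                        f"declared alphabet"
                    )
            else:
                alpha = tuple(sorted(set(observed)))
            self.alphabets[char] = alpha

    @property
    def terminals(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def states(self, char: str) -> pd.Series:
        return self.data[char]

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="terminal")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CharacterMatrix":
        df = pd.read_csv(path, index_col="terminal", dtype=str).fillna(MISSING)
        return cls(df, **kwargs)

    def to_tnt(self, path) -> None:
        """Write a TNT-style block (states recoded to 0..k-1, '?' kept)."""
        lines = [
            "xread",
            f"{len(self.characters)} {len(self.terminals)}",
        ]
        codes = {
            char: {s: str(i) for i, s in enumerate(alpha)}
            for char, alpha in self.alphabets.items()
        }
        for term in self.terminals:
            row = "".join(
                "?" if v in WILDCARDS else codes[c][v]
                for c, v in self.data.loc[term].items()
            )
            lines.append(f"{term.replace(' ', '_')} {row}")
        lines.append(";")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def _leaf_states(
    tree: PhyloTree, column: pd.Series, alphabet: tuple[str, ...], char: str
) -> dict[Node, frozenset[str]]:
    missing_terms = tree.terminal_labels - set(column.index)
    if missing_terms:
        raise ValidationError(
            f"character {char!r}: no cell for terminals "
            f"{sorted(missing_terms)[:5]}"
        )
    if not alphabet:
        raise ValidationError(f"character {char!r} has no observed state")
    full = frozenset(alphabet)
    out = {}
    for label in tree.terminal_labels:
        value = column[label]
        out[tree.terminal(label)] = (
            full if value in WILDCARDS else frozenset([value])
        )
    return out


def fitch_score(
    tree: PhyloTree, column: pd.Series, alphabet: Sequence[str] | None = None
) -> int:
    """Minimum number of unordered state changes for one character.

    Uses Hartigan's downpass, exact on multifurcating trees: each internal
    node keeps the states covered by the largest number of child sets and
    pays one step for every child set not containing them.
    """
    if alphabet is None:
        alphabet = tuple(sorted({v for v in column if v not in WILDCARDS}))
    leaf_sets = _leaf_states(tree, column, tuple(alphabet), column.name)
    score = 0
    sets: dict[Node, frozenset[str]] = {}
    for node in tree.root.postorder():
        if node.is_terminal:
            sets[node] = leaf_sets[node]
            continue
        coverage: dict[str, int] = {}
        for child in node.children:
            for state in sets[child]:
                coverage[state] = coverage.get(state, 0) + 1
        best = max(coverage.values())
        sets[node] = frozenset(s for s, c in coverage.items() if c == best)
        score += len(node.children) - best
    return score


@dataclass
class StateAssignment:
    """One full most-parsimonious reconstruction of a character.

    ``states`` maps every node to a single resolved state; ``cost`` is the
    implied change count (equal to the Fitch score by construction).
    Branches are addressed by the child node's terminal set, which is
    unique within a tree and stable across copies.
    """

    character: str
    flavour: str  # "ACCTRAN" | "DELTRAN"
    states: dict[Node, str]
    cost: int

    def changes(self) -> list[tuple[Node, str, str]]:
        """(child node, from-state, to-state) for every change branch."""
        out = []
        for node, state in self.states.items():
            if node.parent is not None and self.states[node.parent] != state:
                out.append((node, self.states[node.parent], state))
        return out


def _sankoff_costs(
    tree: PhyloTree,
    leaf_sets: dict[Node, frozenset[str]],
    alphabet: tuple[str, ...],
) -> dict[Node, dict[str, float]]:
    inf = float("inf")
    costs: dict[Node, dict[str, float]] = {}
    for node in tree.root.postorder():
        if node.is_terminal:
            allowed = leaf_sets[node]
            costs[node] = {s: (0 if s in allowed else inf) for s in alphabet}
        else:
            table = {}
            for s in alphabet:
                total = 0.0
                for child in node.children:
                    ccost = costs[child]
                    stay = ccost[s]
                    move = min(ccost[t] for t in alphabet) + 1
                    total += min(stay, move)
                table[s] = total
            costs[node] = table
    return costs


def _resolve(
    tree: PhyloTree,
    costs: dict[Node, dict[str, float]],
    alphabet: tuple[str, ...],
    flavour: str,
) -> dict[Node, str]:
    states: dict[Node, str] = {}
    root_costs = costs[tree.root]
    best = min(root_costs.values())
    # root tie broken by alphabet order for both flavours (determinism)
    states[tree.root] = next(s for s in alphabet if root_costs[s] == best)
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        parent_state = states[node.parent]
        table = costs[node]
        options = {}
        for t in alphabet:
            options[t] = table[t] + (0 if t == parent_state else 1)
        opt = min(options.values())
        argmin = [t for t in alphabet if options[t] == opt]
        if flavour == "DELTRAN" or len(argmin) == 1:
            choice = (
                parent_state if parent_state in argmin else argmin[0]
            )
        else:  # ACCTRAN: change as early as possible
            changed = [t for t in argmin if t != parent_state]
            choice = changed[0] if changed else argmin[0]
        states[node] = choice
    return states


def mpr_reconstructions(
    tree: PhyloTree, column: pd.Series, alphabet: Sequence[str] | None = None
) -> tuple[StateAssignment, StateAssignment]:
    """ACCTRAN and DELTRAN reconstructions realizing the Fitch score."""
    if alphabet is None:
        alphabet = tuple(sorted({v for v in column if v not in WILDCARDS}))
    alphabet = tuple(alphabet)
    leaf_sets = _leaf_states(tree, column, alphabet, column.name)
    costs = _sankoff_costs(tree, leaf_sets, alphabet)
    out = []
    for flavour in ("ACCTRAN", "DELTRAN"):
        states = _resolve(tree, costs, alphabet, flavour)
        cost = sum(
            1
            for node, state in states.items()
            if node.parent is not None and states[node.parent] != state
        )
        out.append(
            StateAssignment(
                character=str(column.name),
                flavour=flavour,
                states=states,
                cost=cost,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Transformation classification
# ---------------------------------------------------------------------------

UNIQUE = "unique"
PRIVATE = "private"
NONPRIVATE = "nonprivate"


@dataclass(frozen=True)
class TransformationRecord:
    """One state change on a branch, with its synapomorphy classification.

    ``branch`` is the terminal set subtended by the branch's child node.
    ``classification`` is present only for nonambiguous records on branches
    subtending at least ``min_clade_size`` terminals; smaller or ambiguous
    records are kept with ``classification=None`` (unclassified).
    """

    character: str
    branch: frozenset[str]
    from_state: str
    to_state: str
    ambiguous: bool
    classification: str | None = None

    @property
    def clade_size(self) -> int:
        return len(self.branch)


def _origin_count(assignment: StateAssignment, state: str) -> int:
    """Origins of ``state``: change-events into it, plus the root if ancestral."""
    n = sum(1 for _, _, to in assignment.changes() if to == state)
    root = next(node for node in assignment.states if node.parent is None)
    return n + (1 if assignment.states[root] == state else 0)


def classify_transformations(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    min_clade_size: int = 3,
) -> list[TransformationRecord]:
    """Nonambiguous-transformation records for every character.

    A branch's transformation is nonambiguous iff the ACCTRAN and DELTRAN
    reconstructions agree on its (from, to) pair.  Nonambiguous records on
    branches subtending >= ``min_clade_size`` terminals are classified:

    * ``unique`` — the derived state originates exactly once on the tree
      and every terminal exhibiting it belongs to the clade;
    * ``private`` — multiple origins, but all bearers inside the clade;
    * ``nonprivate`` — terminals outside the clade also bear the state.

    Where the two reconstructions disagree on the number of origins of the
    derived state, the larger count is used (ambiguity resolved toward
    homoplasy).
    """
    if min_clade_size < 1:
        raise ValueError(
            f"min_clade_size must be >= 1, got {min_clade_size}"
        )
    shared = set(matrix.terminals) & tree.terminal_labels
    if shared != tree.terminal_labels:
        raise ValidationError(
            "matrix is missing terminals present in the tree: "
            f"{sorted(tree.terminal_labels - shared)[:5]}"
        )
    records: list[TransformationRecord] = []
    for char in matrix.characters:
        column = matrix.states(char)
        alphabet = matrix.alphabets[char]
        if not alphabet:
            raise ValidationError(f"character {char!r} entirely missing")
        if len(set(alphabet)) == 1:
            continue  # constant character: no transformations possible
        acc, delt = mpr_reconstructions(tree, column, alphabet)
        bearers_of = {
            state: frozenset(
                t for t in tree.terminal_labels if column[t] == state
            )
            for state in alphabet
        }
        acc_changes = {node: (f, t) for node, f, t in acc.changes()}
        del_changes = {node: (f, t) for node, f, t in delt.changes()}
        for node in set(acc_changes) | set(del_changes):
            pair_a = acc_changes.get(node)
            pair_d = del_changes.get(node)
            nonambiguous = pair_a is not None and pair_a == pair_d
            from_state, to_state = pair_a if pair_a is not None else pair_d
            clade = node.terminal_set()
            classification = None
            if nonambiguous and len(clade) >= min_clade_size:
                bearers = bearers_of[to_state]
                if bearers - clade:
                    classification = NONPRIVATE
                else:
                    origins = max(
                        _origin_count(acc, to_state),
                        _origin_count(delt, to_state),
                    )
                    classification = UNIQUE if origins == 1 else PRIVATE
            records.append(
                TransformationRecord(
                    character=char,
                    branch=clade,
                    from_state=from_state,
                    to_state=to_state,
                    ambiguous=not nonambiguous,
                    classification=classification,
                )
            )
    records.sort(
        key=lambda r: (r.character, -len(r.branch), min(r.branch))
    )
    return records


def collapse_unsupported(
    tree: PhyloTree, records: Iterable[TransformationRecord]
) -> PhyloTree:
    """Collapse internal branches lacking any nonambiguous transformation.

    Children of a collapsed node are re-attached to its parent; terminals
    are never removed.  With no supporting records at all the result is a
    star tree (one root polytomy).
    """
    supported = {
        rec.branch for rec in records if not rec.ambiguous
    }
    new = tree.copy()
    # bottom-up so nested unsupported branches collapse correctly
    for node in list(new.root.postorder()):
        if node.is_terminal or node is new.root:
            continue
        if node.terminal_set() not in supported:
            parent = node.parent
            idx = parent.children.index(node)
            for child in node.children:
                child.parent = parent
            parent.children[idx : idx + 1] = node.children
    return PhyloTree(new.root)


def records_to_frame(records: Iterable[TransformationRecord]) -> pd.DataFrame:
    rows = [
        {
            "character": r.character,
            "branch": "|".join(sorted(r.branch)),
            "clade_size": r.clade_size,
            "from": r.from_state,
            "to": r.to_state,
            "ambiguous": r.ambiguous,
            "classification": r.classification or "",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "character",
            "branch",
            "clade_size",
            "from",
            "to",
            "ambiguous",
            "classification",
        ],
    )


def write_records_csv(records: Iterable[TransformationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def classification_summary(
    records: Iterable[TransformationRecord],
) -> dict[str, int]:
    """Counts per classification, always including explicit zeros."""
    summary = {UNIQUE: 0, PRIVATE: 0, NONPRIVATE: 0, "unclassified": 0,
               "ambiguous": 0}
    for rec in records:
        if rec.ambiguous:
            summary["ambiguous"] += 1
        elif rec.classification is None:
            summary["unclassified"] += 1
        else:
            summary[rec.classification] += 1
    return summary
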