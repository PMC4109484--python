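"""Core data model: concept identifiers, concept trees, names and synonyms.

A *taxonomic concept* is a scientific name anchored to a publication whose
circumscription -- the set of populations the usage denotes -- can be inferred
from that source.  Mutually congruent concepts form a cluster that receives a
single opaque identifier (a 16-character uppercase hexadecimal key), so that
relationships need only be recorded between identifiers, never between the far
more numerous individual name usages.

Identifiers are organised into rooted *concept trees* whose parent-child edges
express strict circumscription inclusion.  A tree may carry several mutually
contradictory *variants* (alternate arrangements); all variants of a tree
share the same root and the same terminal nodes, and any intermediate node
that appears in more than one variant denotes the same set of terminals in
each.  Names are attached to concepts twice over: as rank-tagged labels on the
concept itself (how a publication used the name) and as rows of a synonym
table, which together drive name -> concept lookup.
"""

from __future__ import annotations

import re
import secrets
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import networkx as nx

from .errors import StructuralError, UnknownConceptError, UnknownNodeError

__all__ = [
    "Rank",
    "Kind",
    "NameType",
    "NameUsage",
    "ConceptNode",
    "SynonymEntry",
    "TreeVariant",
    "TreeSet",
    "ConceptStore",
    "is_concept_id",
    "new_concept_id",
    "canonicalize_name",
]

_ID_RE = re.compile(r"^[0-9A-F]{16}$")
_HEX = "0123456789ABCDEF"


class Rank(str, Enum):
    """Rank at which a name usage appears in a checklist."""

    SPECIES = "species"
    SUBSPECIES = "subspecies"
    OTHER = "other"


class Kind(str, Enum):
    """How a concept was originally circumscribed when first registered."""

    SPECIES = "species"
    SUBSPECIES = "subspecies"
    GROUP = "group"
    OTHER = "other"


class NameType(str, Enum):
    SCIENTIFIC = "scientific"
    VERNACULAR = "vernacular"


def is_concept_id(value: object) -> bool:
    """True if *value* is a well-formed concept identifier."""
    return isinstance(value, str) and bool(_ID_RE.match(value))


def new_concept_id(rng=None, existing: Iterable[str] = ()) -> str:
    """Draw a fresh 16-hex-character identifier.

    With a seeded ``random.Random`` instance the sequence is reproducible;
    without one a cryptographic source is used.  A collision with *existing*
    triggers a silent re-draw.
    """
    taken = set(existing)
    while True:
        if rng is None:
            cid = secrets.token_hex(8).upper()
        else:
            cid = "".join(rng.choice(_HEX) for _ in range(16))
        if cid not in taken:
            return cid


def canonicalize_name(name: str) -> str:
    """Canonical form of a scientific name: whitespace collapsed, genus
    capitalized, epithets lower-cased.  Idempotent; exact-string matching only
    (no fuzzy matching)."""
    parts = name.split()
    if not parts:
        return ""
    head = parts[0][:1].upper() + parts[0][1:].lower()
    return " ".join([head] + [p.lower() for p in parts[1:]])


@dataclass(frozen=True)
class NameUsage:
    """A name attached to a concept at a given rank."""

    name: str
    rank: Rank = Rank.SPECIES


@dataclass
class ConceptNode:
    """A distinct circumscription cluster and the names historically attached
    to it.  Monotypic species and their nominal subspecies are one concept
    with two rank-tagged labels (label aliasing), never duplicate nodes."""

    id: str
    kind: Kind = Kind.SPECIES
    names: list[NameUsage] = field(default_factory=list)

    @property
    def display_names(self) -> list[str]:
        return [u.name for u in self.names]


@dataclass(frozen=True)
class SynonymEntry:
    name: str
    concept: str
    name_type: NameType = NameType.SCIENTIFIC
    language: Optional[str] = None


class TreeVariant:
    """One rooted arrangement of a concept tree.

    ``edges`` maps a parent identifier to the unordered set of its children.
    Construction is lenient -- malformed structures (cycles, several roots,
    shared children) are representable so that validation can *report* them --
    but :attr:`root` raises :class:`StructuralError` when the structure is not
    a single rooted tree.  A single-node variant is expressed by empty edges
    plus the node in *extra_nodes*.
    """

    __slots__ = ("_edges", "_nodes", "_parents", "_roots", "_leafsets")

    def __init__(self, edges: Mapping[str, Iterable[str]], extra_nodes: Iterable[str] = ()):
        self._edges: dict[str, frozenset[str]] = {
            p: frozenset(cs) for p, cs in dict(edges).items() if cs
        }
        nodes: set[str] = set(self._edges)
        for cs in self._edges.values():
            nodes |= cs
        nodes.update(extra_nodes)
        self._nodes = frozenset(nodes)
        parents: dict[str, list[str]] = {}
        for p in sorted(self._edges):
            for c in self._edges[p]:
                parents.setdefault(c, []).append(p)
        self._parents = parents
        self._roots = tuple(sorted(self._nodes - set(parents)))
        self._leafsets: dict[str, frozenset[str]] = {}

    @property
    def edges(self) -> dict[str, frozenset[str]]:
        return dict(self._edges)

    @property
    def nodes(self) -> frozenset[str]:
        return self._nodes

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(n for n in self._nodes if n not in self._edges)

    def __contains__(self, node: object) -> bool:
        return node in self._nodes

    def children(self, node: str) -> frozenset[str]:
        return self._edges.get(node, frozenset())

    def parent(self, node: str) -> Optional[str]:
        ps = self._parents.get(node, [])
        return ps[0] if ps else None

    def structural_problems(self) -> list[str]:
        """Human-readable list of reasons this is not a single rooted tree."""
        probs: list[str] = []
        if not self._nodes:
            probs.append("variant has no nodes")
            return probs
        if len(self._roots) != 1:
            probs.append(f"expected exactly one root, found {len(self._roots)}: "
                         f"{list(self._roots)}")
        multi = sorted(c for c, ps in self._parents.items() if len(ps) > 1)
        if multi:
            probs.append(f"nodes with more than one parent: {multi}")
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from((p, c) for p, cs in self._edges.items() for c in cs)
        if not nx.is_directed_acyclic_graph(g):
            probs.append("edges contain a cycle")
        return probs

    @property
    def root(self) -> str:
        probs = self.structural_problems()
        if probs:
            raise StructuralError("; ".join(probs))
        return self._roots[0]

    def leaf_set(self, node: str) -> frozenset[str]:
        """Terminal nodes descended from *node* (itself if terminal)."""
        if node not in self._nodes:
            raise UnknownNodeError(node)
        cached = self._leafsets.get(node)
        if cached is not None:
            return cached
        out: set[str] = set()
        seen: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            cs = self._edges.get(n)
            if cs:
                stack.extend(cs)
            else:
                out.add(n)
        result = frozenset(out)
        self._leafsets[node] = result
        return result

    def ancestors(self, node: str) -> tuple[str, ...]:
        """Strict ancestors of *node*, nearest first."""
        if node not in self._nodes:
            raise UnknownNodeError(node)
        out: list[str] = []
        seen = {node}
        cur = self.parent(node)
        while cur is not None and cur not in seen:
            out.append(cur)
            seen.add(cur)
            cur = self.parent(cur)
        return tuple(out)

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if *a* is a strict ancestor of *b*."""
        return a in self.ancestors(b)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TreeVariant):
            return NotImplemented
        return self._edges == other._edges and self._nodes == other._nodes

    def __hash__(self) -> int:
        return hash((frozenset(self._edges.items()), self._nodes))

    def __repr__(self) -> str:
        return f"TreeVariant({len(self._nodes)} nodes, root={self._roots})"


@dataclass
class TreeSet:
    """One root concept plus one or more alternate tree variants over shared
    terminals."""

    root: str
    variants: list[TreeVariant]

    @property
    def nodes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for v in self.variants:
            out |= v.nodes
        return out

    @property
    def leaves(self) -> frozenset[str]:
        return self.variants[0].leaf_set(self.root)

    def variants_with(self, node: str) -> list[int]:
        return [i for i, v in enumerate(self.variants) if node in v]

    def leaf_set(self, node: str) -> frozenset[str]:
        """Terminal descendants of *node*; identical in every variant that
        contains it (enforced by the validator)."""
        for v in self.variants:
            if node in v:
                return v.leaf_set(node)
        raise UnknownNodeError(node)

    def __contains__(self, node: object) -> bool:
        return any(node in v for v in self.variants)


@dataclass
class ConceptStore:
    """Concept identifiers, their trees, labels, synonyms and hybrid links.

    Hybrids are concepts linked to two or more parental concepts; they sit
    outside every tree variant and are therefore never weighted or summed.
    """

    treesets: list[TreeSet] = field(default_factory=list)
    concepts: dict[str, ConceptNode] = field(default_factory=dict)
    synonyms: list[SynonymEntry] = field(default_factory=list)
    hybrids: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self._idx_node: dict[str, TreeSet] | None = None
        self._idx_name: dict[str, set[str]] | None = None

    # -- bookkeeping -------------------------------------------------------

    def _touch(self) -> None:
        self._idx_node = None
        self._idx_name = None

    def ids(self) -> set[str]:
        out = set(self.concepts)
        for ts in self.treesets:
            out |= ts.nodes
        return out

    def new_id(self, rng=None) -> str:
        return new_concept_id(rng, self.ids())

    # -- registration ------------------------------------------------------

    def add_concept(self, cid: str, kind: Kind = Kind.SPECIES,
                    names: Iterable[NameUsage] = ()) -> ConceptNode:
        if not is_concept_id(cid):
            raise ValueError(f"not a valid concept identifier: {cid!r}")
        if cid in self.concepts:
            raise ValueError(f"concept already registered: {cid}")
        node = ConceptNode(cid, Kind(kind), list(names))
        self.concepts[cid] = node
        self._touch()
        return node

    def add_name(self, cid: str, name: str, rank: Rank = Rank.SPECIES) -> None:
        node = self.concepts.get(cid)
        if node is None:
            raise UnknownConceptError(cid)
        usage = NameUsage(name, Rank(rank))
        if usage not in node.names:
            node.names.append(usage)
        self._touch()

    def add_synonym(self, name: str, concept: str,
                    name_type: NameType = NameType.SCIENTIFIC,
                    language: Optional[str] = None) -> None:
        if concept not in self.concepts:
            raise UnknownConceptError(concept)
        entry = SynonymEntry(name, concept, NameType(name_type), language)
        if entry not in self.synonyms:
            self.synonyms.append(entry)
        self._touch()

    def add_treeset(self, ts: TreeSet) -> None:
        unknown = sorted(ts.nodes - set(self.concepts))
        if unknown:
            raise UnknownConceptError(f"tree nodes not registered as concepts: {unknown}")
        claimed = set()
        for other in self.treesets:
            claimed |= other.nodes
        overlap = sorted(ts.nodes & claimed)
        if overlap:
            raise ValueError(f"nodes already belong to another tree: {overlap}")
        self.treesets.append(ts)
        self._touch()

    def replace_treeset(self, old_root: str, new_ts: TreeSet) -> None:
        for i, ts in enumerate(self.treesets):
            if ts.root == old_root:
                self.treesets[i] = new_ts
                self._touch()
                return
        raise UnknownConceptError(old_root)

    def remove_treeset(self, root: str) -> TreeSet:
        for i, ts in enumerate(self.treesets):
            if ts.root == root:
                self._touch()
                return self.treesets.pop(i)
        raise UnknownConceptError(root)

    def add_hybrid(self, cid: str, parents: Iterable[str]) -> None:
        parents = tuple(sorted(parents))
        if len(parents) < 2:
            raise ValueError("a hybrid links two or more concepts")
        for p in parents:
            if p not in self.concepts:
                raise UnknownConceptError(p)
        if cid not in self.concepts:
            self.add_concept(cid, Kind.OTHER)
        self.hybrids[cid] = parents
        self._touch()

    # -- queries -----------------------------------------------------------

    def treeset_for(self, cid: str) -> Optional[TreeSet]:
        if self._idx_node is None:
            idx: dict[str, TreeSet] = {}
            for ts in self.treesets:
                for n in ts.nodes:
                    idx[n] = ts
            self._idx_node = idx
        return self._idx_node.get(cid)

    def leaf_set(self, cid: str) -> frozenset[str]:
        """Terminal concepts subtended by *cid*; a concept outside every tree
        is its own (singleton) circumscription."""
        ts = self.treeset_for(cid)
        if ts is not None:
            return ts.leaf_set(cid)
        if cid in self.concepts:
            return frozenset({cid})
        raise UnknownConceptError(cid)

    def lookup_name(self, name: str) -> frozenset[str]:
        """All concept IDs bearing *name* (after canonicalization), via both
        concept labels and the synonym table.  Empty set if unknown."""
        if self._idx_name is None:
            idx: dict[str, set[str]] = {}
            for cid, node in self.concepts.items():
                for usage in node.names:
                    idx.setdefault(canonicalize_name(usage.name), set()).add(cid)
            for entry in self.synonyms:
                idx.setdefault(canonicalize_name(entry.name), set()).add(entry.concept)
            self._idx_name = idx
        return frozenset(self._idx_name.get(canonicalize_name(name), ()))
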