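"""Append-only edits of concept trees.

Published concepts are permanent: an edit never deletes a node and never
changes the circumscription an existing identifier denotes.  New
circumscriptions always receive new identifiers.  Because a model that
minimizes the number of alternate trees is preferable, refining a terminal
(:func:`split_terminal`) and joining independent trees (:func:`merge_roots`)
modify every variant in place and create no new variant; only
:func:`group_children` and :func:`reassign` -- which genuinely contradict the
existing arrangement -- append an alternate variant.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .errors import EditError, UnknownConceptError
from .store import ConceptStore, Kind, Rank, TreeSet, TreeVariant

__all__ = ["split_terminal", "merge_roots", "group_children", "reassign", "elevate"]


def split_terminal(leaf: str, n_children: int, store: ConceptStore,
                   rng=None, kind: Kind = Kind.SUBSPECIES) -> list[str]:
    """Resolve a terminal concept into *n_children* new finer concepts.

    The former terminal keeps its identifier and its meaning (its leaf set is
    refined, not changed); every variant is extended identically, so no new
    variant appears.  Returns the new identifiers.
    """
    if n_children < 2:
        raise EditError("a split needs at least two children")
    ts = store.treeset_for(leaf)
    if ts is None:
        raise UnknownConceptError(leaf)
    if leaf not in ts.leaves:
        raise EditError(f"{leaf} is an internal node; only terminals can be split")
    new_ids = []
    for _ in range(n_children):
        cid = store.new_id(rng)
        store.add_concept(cid, kind)
        new_ids.append(cid)
    new_variants = [
        TreeVariant({**v.edges, leaf: frozenset(new_ids)}) for v in ts.variants
    ]
    store.replace_treeset(ts.root, TreeSet(ts.root, new_variants))
    return new_ids


def merge_roots(a_root: str, b_root: str, store: ConceptStore,
                rng=None, kind: Kind = Kind.GROUP) -> str:
    """Join two independent trees under a new common root concept.

    The two trees must not share nodes; variants are combined pairwise, so a
    tree with *m* variants merged with one of *n* variants yields ``m * n``
    variants (typically 1 x 1).  Returns the new root identifier.
    """
    ts_a = store.treeset_for(a_root)
    ts_b = store.treeset_for(b_root)
    if ts_a is None:
        raise UnknownConceptError(a_root)
    if ts_b is None:
        raise UnknownConceptError(b_root)
    if ts_a is ts_b:
        raise EditError("cannot merge a tree with itself")
    if ts_a.root != a_root or ts_b.root != b_root:
        raise EditError("merge_roots expects the root concepts of two trees")
    new_root = store.new_id(rng)
    store.add_concept(new_root, kind)
    variants = [
        TreeVariant({**va.edges, **vb.edges, new_root: frozenset({a_root, b_root})})
        for va in ts_a.variants
        for vb in ts_b.variants
    ]
    store.remove_treeset(a_root)
    store.remove_treeset(b_root)
    store.add_treeset(TreeSet(new_root, variants))
    return new_root


def group_children(parent: str, subset: Iterable[str], store: ConceptStore,
                   variant_index: int = 0, rng=None,
                   kind: Kind = Kind.GROUP) -> str:
    """Lump a proper subset of a parent's children under a new intermediate
    concept, as an *alternate* arrangement.

    The chosen variant is left untouched; a new variant is appended in which
    the subset hangs under the new node.  Returns the new identifier.
    """
    subset = frozenset(subset)
    ts = store.treeset_for(parent)
    if ts is None:
        raise UnknownConceptError(parent)
    try:
        base = ts.variants[variant_index]
    except IndexError:
        raise EditError(f"variant {variant_index} does not exist") from None
    children = base.children(parent)
    if not children:
        raise EditError(f"{parent} has no children in variant {variant_index}")
    if not subset <= children:
        raise EditError("subset must consist of current children of the parent")
    if len(subset) < 2:
        raise EditError("grouping a single child would duplicate its circumscription")
    if subset == children:
        raise EditError("grouping all children would duplicate the parent")
    new_id = store.new_id(rng)
    store.add_concept(new_id, kind)
    edges = base.edges
    edges[parent] = (children - subset) | {new_id}
    edges[new_id] = subset
    new_variants = list(ts.variants) + [TreeVariant(edges)]
    store.replace_treeset(ts.root, TreeSet(ts.root, new_variants))
    return new_id


def _carve(variant: TreeVariant, node: str, keep: frozenset[str]) -> list[str]:
    """Maximal descendants of *node* whose leaf sets lie entirely in *keep*.

    These are the existing nodes that can be reused intact under a new parent
    without changing their meaning.
    """
    if variant.leaf_set(node) <= keep:
        return [node]
    out: list[str] = []
    for child in sorted(variant.children(node)):
        if variant.leaf_set(child) & keep:
            out.extend(_carve(variant, child, keep))
    return out


def reassign(moved_leaves: Iterable[str], from_species: str, to_species: str,
             store: ConceptStore, rng=None,
             variant_index: Optional[int] = None) -> dict[str, Optional[str]]:
    """Move terminal concepts from one species to another, as a new variant.

    Creates (if needed) a common root covering both species, then appends a
    variant containing new concepts A' (= recipient's leaves plus the moved
    ones) and B' (= donor's leaves minus the moved ones).  If B' collapses to
    a single terminal, that terminal's existing identifier is reused -- the
    circumscriptions are congruent.  The original arrangement stays intact.

    The new variant is derived from *variant_index* (an index into the tree's
    variants after any merge) or, by default, from the most recent variant
    containing both species.

    Returns ``{"new_root": id-or-None, "a_prime": id, "b_prime": id}``.
    """
    moved = frozenset(moved_leaves)
    if not moved:
        raise EditError("no leaves to move")
    ts_from = store.treeset_for(from_species)
    ts_to = store.treeset_for(to_species)
    if ts_from is None:
        raise UnknownConceptError(from_species)
    if ts_to is None:
        raise UnknownConceptError(to_species)
    from_leaves = ts_from.leaf_set(from_species)
    if not moved <= from_leaves:
        raise EditError("moved leaves must belong to the source species")
    if moved == from_leaves:
        raise EditError("moving every leaf is a lump, not a reassignment")
    if ts_from is ts_to and store.leaf_set(to_species) & from_leaves:
        raise EditError("source and target circumscriptions overlap")

    new_root: Optional[str] = None
    if ts_from is not ts_to:
        new_root = merge_roots(ts_from.root, ts_to.root, store, rng)
        ts = store.treeset_for(new_root)
    else:
        ts = ts_from
        if from_species == ts.root or to_species == ts.root:
            raise EditError("cannot reassign into or out of the tree root")
    assert ts is not None

    if variant_index is not None:
        try:
            base = ts.variants[variant_index]
        except IndexError:
            raise EditError(f"variant {variant_index} does not exist") from None
        if from_species not in base or to_species not in base:
            raise EditError(
                f"variant {variant_index} does not contain both species")
    else:
        base = None
        for v in reversed(ts.variants):
            if from_species in v and to_species in v:
                base = v
                break
        if base is None:
            raise EditError("no variant contains both species")

    keep_b = from_leaves - moved
    a_children = [to_species] + _carve(base, from_species, moved)
    b_parts = _carve(base, from_species, keep_b)

    a_prime = store.new_id(rng)
    store.add_concept(a_prime, Kind.SPECIES)
    if len(b_parts) == 1:
        b_prime = b_parts[0]
    else:
        b_prime = store.new_id(rng)
        store.add_concept(b_prime, Kind.SPECIES)

    if base.parent(from_species) is None or base.parent(to_species) is None:
        raise EditError("cannot reassign into or out of the tree root")

    edges = base.edges
    # Drop the donor and any nodes above the intact boundary inside it.
    intact = set(_carve(base, from_species, moved)) | set(b_parts)
    stack = [from_species]
    while stack:
        n = stack.pop()
        if n in intact:
            continue
        for c in base.children(n):
            stack.append(c)
        edges.pop(n, None)

    # Every ancestor strictly between the two species and their nearest
    # common ancestor would gain or lose the moved leaves, i.e. silently
    # denote a different circumscription; such nodes are left out of the new
    # variant and their unaffected children re-hang under the common
    # ancestor, whose own leaf set is untouched.
    anc_from = [from_species, *base.ancestors(from_species)]
    anc_to = [to_species, *base.ancestors(to_species)]
    common = next(n for n in anc_from if n in set(anc_to))
    chain_from = anc_from[1:anc_from.index(common)]
    chain_to = anc_to[1:anc_to.index(common)]
    rehang: set[str] = set()
    for chain, bottom in ((chain_from, from_species), (chain_to, to_species)):
        prev = bottom
        for node in chain:
            rehang |= edges.pop(node) - {prev}
            prev = node
    top_from = chain_from[-1] if chain_from else from_species
    top_to = chain_to[-1] if chain_to else to_species
    edges[common] = (edges[common] - {top_from, top_to}) \
        | {a_prime, b_prime} | rehang
    edges[a_prime] = frozenset(a_children)
    if len(b_parts) > 1:
        edges[b_prime] = frozenset(b_parts)

    new_variants = list(ts.variants) + [TreeVariant(edges)]
    store.replace_treeset(ts.root, TreeSet(ts.root, new_variants))
    return {"new_root": new_root, "a_prime": a_prime, "b_prime": b_prime}


def elevate(concept: str, name: str, store: ConceptStore,
            rank: Rank = Rank.SPECIES) -> None:
    """Record that *concept* is now also used at *rank* under *name*.

    Elevating a subspecies to a full species changes no circumscription and
    therefore no tree: the concept simply gains a species-rank label (e.g. the
    former nominal subspecies starts bearing the bare binomial).
    """
    store.add_name(concept, name, rank)
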