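"""Pairwise concept relationships derived from leaf-set algebra.

Because distinct identifiers within one tree always denote distinct leaf
sets, the classic concept predicates (congruent, includes, included in,
overlaps, excludes) reduce to set algebra over terminal nodes.  Concepts that
have never been co-modelled under a shared root are reported as *unrelated*
rather than *excludes*: the store cannot certify disjointness of
circumscriptions it has never placed in one tree.
"""

from __future__ import annotations

from enum import Enum

from .errors import UnknownConceptError
from .store import ConceptStore

__all__ = ["Verdict", "relate"]


class Verdict(str, Enum):
    CONGRUENT = "congruent"
    INCLUDES = "includes"
    INCLUDED_IN = "included_in"
    OVERLAPS = "overlaps"
    EXCLUDES = "excludes"
    UNRELATED = "unrelated"


def relate(a: str, b: str, store: ConceptStore) -> Verdict:
    """Relationship of concept *a* to concept *b*.

    ``includes(a, b)`` iff a's leaf set strictly contains b's;
    ``overlaps`` iff the leaf sets intersect without containment;
    ``excludes`` iff they are disjoint within one shared tree;
    ``unrelated`` iff the concepts live in different trees (or outside any).
    """
    for cid in (a, b):
        if cid not in store.concepts and store.treeset_for(cid) is None:
            raise UnknownConceptError(cid)
    if a == b:
        return Verdict.CONGRUENT
    ts_a = store.treeset_for(a)
    ts_b = store.treeset_for(b)
    if ts_a is None or ts_b is None or ts_a is not ts_b:
        return Verdict.UNRELATED
    la = store.leaf_set(a)
    lb = store.leaf_set(b)
    if la == lb:
        # Distinct IDs in one tree never share a leaf set (store premise),
        # but answer honestly if handed such a structure.
        return Verdict.CONGRUENT
    if lb < la:
        return Verdict.INCLUDES
    if la < lb:
        return Verdict.INCLUDED_IN
    if la & lb:
        return Verdict.OVERLAPS
    return Verdict.EXCLUDES
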