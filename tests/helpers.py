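"""Shared test utilities: random tree generation and an independent
brute-force oracle for the assignment search."""

from __future__ import annotations

import itertools
import random
from fractions import Fraction

from taxonconcept import (Checklist, ConceptStore, MappingStatus, Rank,
                          TreeVariant, new_concept_id)


def random_variant(rng: random.Random, max_depth: int = 4,
                   max_children: int = 4) -> TreeVariant:
    """A random rooted tree with >=2 children per internal node."""
    edges: dict[str, list[str]] = {}
    taken: set[str] = set()

    def fresh() -> str:
        cid = new_concept_id(rng, taken)
        taken.add(cid)
        return cid

    root = fresh()

    def grow(node: str, depth: int) -> None:
        if depth > 0 and rng.random() < 0.7:
            kids = [fresh() for _ in range(rng.randint(2, max_children))]
            edges[node] = kids
            for c in kids:
                grow(c, depth - 1)

    grow(root, max_depth)
    return TreeVariant(edges, extra_nodes=(root,))


# ---------------------------------------------------------------------------
# brute-force oracle for solve_assignment
#
# Recomputes everything from first principles: its own weight recursion, its
# own ancestor walk, and a flat product over every record's candidates with
# no grouping, pruning or sharing with the implementation under test.


def _bf_weights(edges: dict, node: str, w: Fraction, out: dict) -> None:
    out[node] = w
    kids = edges.get(node, ())
    for c in kids:
        _bf_weights(edges, c, w / len(kids), out)


def _bf_is_ancestor(edges: dict, a: str, b: str) -> bool:
    frontier = list(edges.get(a, ()))
    while frontier:
        n = frontier.pop()
        if n == b:
            return True
        frontier.extend(edges.get(n, ()))
    return False


def brute_force_solutions(checklist: Checklist, candidates: dict,
                          store: ConceptStore) -> set[frozenset]:
    """All full assignments (over records with in-tree candidates) that pass
    the weight-sum and branch/descendant rules in >= 1 variant per tree."""
    records = [r for r in checklist.records
               if any(store.treeset_for(c) for c in candidates[r.taxon_id])]
    cand_lists = [sorted(c for c in candidates[r.taxon_id]
                         if store.treeset_for(c) is not None)
                  for r in records]
    solutions: set[frozenset] = set()
    for combo in itertools.product(*cand_lists):
        mapping = dict(zip((r.taxon_id for r in records), combo))
        # rule 4
        ok = True
        for cid in set(combo):
            holders = [r for r in records if mapping[r.taxon_id] == cid]
            if len(holders) == 1:
                continue
            if len(holders) != 2:
                ok = False
                break
            sp = [r for r in holders if r.rank is Rank.SPECIES]
            sub = [r for r in holders if r.rank is Rank.SUBSPECIES]
            if not (len(sp) == 1 and len(sub) == 1
                    and sub[0].parent_taxon_id == sp[0].taxon_id):
                ok = False
                break
        if not ok:
            continue
        touched = {}
        for cid in combo:
            ts = store.treeset_for(cid)
            touched.setdefault(ts.root, ts)
        good = True
        for root, ts in touched.items():
            recs = [r for r in records
                    if store.treeset_for(mapping[r.taxon_id]).root == root]
            variant_ok = False
            for variant in ts.variants:
                edges = {p: sorted(cs) for p, cs in variant.edges.items()}
                weights: dict[str, Fraction] = {}
                _bf_weights(edges, root, Fraction(1), weights)
                if any(mapping[r.taxon_id] not in weights for r in recs):
                    continue
                # rule 5
                bad = False
                for ra, rb in itertools.combinations(recs, 2):
                    if ra.rank is rb.rank:
                        ca, cb = mapping[ra.taxon_id], mapping[rb.taxon_id]
                        if ca != cb and (_bf_is_ancestor(edges, ca, cb)
                                         or _bf_is_ancestor(edges, cb, ca)):
                            bad = True
                            break
                if bad:
                    continue
                # rule 1
                sp = [r for r in recs if r.rank is Rank.SPECIES]
                if sp and sum(weights[mapping[r.taxon_id]] for r in sp) != 1:
                    continue
                # rule 3
                for r in sp:
                    subs = [s for s in checklist.children_of(r.taxon_id)
                            if s.rank is Rank.SUBSPECIES]
                    if not subs or any(s.taxon_id not in mapping for s in subs):
                        continue
                    if sum(weights[mapping[s.taxon_id]] for s in subs) \
                            != weights[mapping[r.taxon_id]]:
                        bad = True
                        break
                if bad:
                    continue
                # rule 6
                for r in recs:
                    pid = r.parent_taxon_id
                    if pid is None or pid not in mapping:
                        continue
                    pc, cc = mapping[pid], mapping[r.taxon_id]
                    if pc == cc:
                        sibs = [s for s in checklist.children_of(pid)
                                if s.rank is Rank.SUBSPECIES]
                        if not (r.rank is Rank.SUBSPECIES and len(sibs) == 1):
                            bad = True
                            break
                    elif pc not in weights \
                            or not _bf_is_ancestor(edges, pc, cc):
                        bad = True
                        break
                if not bad:
                    variant_ok = True
                    break
            if not variant_ok:
                good = False
                break
        if good:
            solutions.add(frozenset(mapping.items()))
    return solutions


def expected_statuses(checklist: Checklist, candidates: dict,
                      store: ConceptStore, solutions: set[frozenset]) -> dict:
    """Per-record (status, concept) implied by a brute-force solution set."""
    out = {}
    sols = [dict(s) for s in solutions]
    for r in checklist.records:
        in_tree = sorted(c for c in candidates[r.taxon_id]
                         if store.treeset_for(c) is not None)
        if not in_tree:
            out[r.taxon_id] = (MappingStatus.UNMAPPED_NEW, None)
        elif not sols:
            out[r.taxon_id] = (MappingStatus.CONFLICT, None)
        else:
            ids = sorted({s[r.taxon_id] for s in sols})
            if len(ids) == 1:
                out[r.taxon_id] = (MappingStatus.MAPPED, ids[0])
            else:
                out[r.taxon_id] = (MappingStatus.AMBIGUOUS, None)
    return out


def collapsed_leaf_set(store: ConceptStore, cid: str,
                       refinement: dict[str, str]) -> frozenset:
    """Leaf set of *cid* with refined terminals mapped back onto the concept
    they refine (for comparing leaf sets across a terminal split)."""
    out = set()
    for leaf in store.leaf_set(cid):
        while leaf in refinement:
            leaf = refinement[leaf]
        out.add(leaf)
    return frozenset(out)
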