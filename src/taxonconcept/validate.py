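"""Rule-numbered validation of concept trees and checklist mappings.

Seven consistency rules follow from the data model:

1. species-level weights within a tree sum to exactly the scope-adjusted
   total in at least one variant and never exceed it in any;
2. only a single candidate assignment attains that total;
3. the subspecies of a species sum to the species' own weight;
4. at most one record per checklist maps to a given concept ID (monotypic
   species and their nominal subspecies excepted -- one ID, two labels);
5. no two same-rank records sit on one ancestor-descendant branch;
6. parent links in the checklist mirror tree ancestry;
7. alternate variants share root and terminals, and shared intermediate
   nodes keep the same terminal descendants everywhere.

Rules 1-3 are defined for species/subspecies sums, so "other"-rank records
are exempt from them but still subject to rules 4-6.  All findings are
advisory report entries, never hard stops: a violation points either at a
mis-mapped checklist or at a mis-constructed tree, and fixing either is a
curation decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .errors import CombinationBudgetError
from .mapper import (Checklist, MappingResult, MappingStatus,
                     _enumerate_group, _search_groups, _variant_tables,
                     resolve_candidates, DEFAULT_COMBINATION_CAP)
from .store import ConceptStore, Rank, TreeSet

__all__ = ["Violation", "ValidationReport", "validate_treeset", "validate_mapping"]


@dataclass(frozen=True, order=True)
class Violation:
    rule: int
    subjects: tuple[str, ...]
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def __post_init__(self):
        self.violations.sort()

    @property
    def ok(self) -> bool:
        return not self.violations

    def rules(self) -> set[int]:
        return {v.rule for v in self.violations}

    def __iter__(self):
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)


# ---------------------------------------------------------------------------
# tree-level checks (rule 7 plus structure)


def validate_treeset(treeset: TreeSet) -> ValidationReport:
    """Check a tree's variants for structural soundness and rule 7.

    Malformed input produces report entries, not exceptions.
    """
    found: list[Violation] = []
    usable: list[int] = []
    for i, v in enumerate(treeset.variants):
        probs = v.structural_problems()
        for p in probs:
            found.append(Violation(7, (treeset.root,), f"variant {i}: structure: {p}"))
        if probs:
            continue
        usable.append(i)
        if v.root != treeset.root:
            found.append(Violation(
                7, (treeset.root, v.root),
                f"variant {i}: root {v.root} differs from declared root"))
        for node in v.nodes:
            nc = len(v.children(node))
            if nc == 1:
                found.append(Violation(
                    7, (node,),
                    f"variant {i}: node {node} has a single child (a one-child "
                    f"node duplicates its child's circumscription)"))

    # cross-variant checks need at least two structurally sound variants
    sound = [treeset.variants[i] for i in usable]
    if len(sound) >= 2:
        ref = sound[0]
        ref_terminals = ref.leaf_set(ref.root)
        for i, v in zip(usable[1:], sound[1:]):
            terms = v.leaf_set(v.root)
            if terms != ref_terminals:
                diff = sorted(terms ^ ref_terminals)
                found.append(Violation(
                    7, tuple(diff),
                    f"variant {i}: terminal nodes differ from variant {usable[0]}"))
        for a_pos in range(len(sound)):
            for b_pos in range(a_pos + 1, len(sound)):
                va, vb = sound[a_pos], sound[b_pos]
                for node in sorted(va.nodes & vb.nodes):
                    if va.leaf_set(node) != vb.leaf_set(node):
                        found.append(Violation(
                            7, (node,),
                            f"node {node} has different terminal descendants in "
                            f"variants {usable[a_pos]} and {usable[b_pos]}"))
    return ValidationReport(found)


# ---------------------------------------------------------------------------
# mapping-level checks (rules 1-6)


def validate_mapping(checklist: Checklist, mapping: MappingResult,
                     store: ConceptStore,
                     cap: int = DEFAULT_COMBINATION_CAP) -> ValidationReport:
    """Check a checklist-to-concept mapping against rules 1-6."""
    found: list[Violation] = []
    by_id = mapping.by_id
    mapped = [(r, by_id[r.taxon_id].concept) for r in checklist.records
              if r.taxon_id in by_id and by_id[r.taxon_id].concept is not None]

    # rule 4 -- across the whole checklist
    holders: dict[str, list] = {}
    for r, c in mapped:
        holders.setdefault(c, []).append(r)
    for c, recs in sorted(holders.items()):
        if len(recs) == 1:
            continue
        if len(recs) == 2:
            a, b = sorted(recs, key=lambda r: r.rank.value)
            if a.rank is Rank.SPECIES and b.rank is Rank.SUBSPECIES \
                    and b.parent_taxon_id == a.taxon_id:
                continue  # monotypic nominal alias
        found.append(Violation(
            4, tuple(sorted(r.taxon_id for r in recs)),
            f"concept {c} is mapped by {len(recs)} records"))

    # group records per tree
    per_root: dict[str, list] = {}
    for r, c in mapped:
        ts = store.treeset_for(c)
        if ts is not None:
            per_root.setdefault(ts.root, []).append((r, c))

    for root in sorted(per_root):
        ts = store.treeset_for(root)
        tables = _variant_tables(ts, checklist.scope)
        pairs = per_root[root]

        # rule 1 -- species usages tile the tree in >= 1 variant, never exceed
        species = [(r, c) for r, c in pairs if r.rank is Rank.SPECIES]
        if species:
            attained = False
            exceeded: list[int] = []
            for vi, weights in enumerate(tables):
                if weights is None or any(c not in weights for _, c in species):
                    continue
                total = sum((weights[c] for _, c in species), Fraction(0))
                if total == 1:
                    attained = True
                elif total > 1:
                    exceeded.append(vi)
            subjects = tuple(sorted(c for _, c in species))
            if not attained:
                found.append(Violation(
                    1, subjects,
                    f"tree {root}: species weights do not sum to the scope "
                    f"total in any variant"))
            for vi in exceeded:
                found.append(Violation(
                    1, subjects,
                    f"tree {root}: species weights exceed the scope total in "
                    f"variant {vi}"))

        # rule 3 -- subspecies sum to their species' weight in some variant
        mapped_ids = {r.taxon_id: c for r, c in pairs}
        for r, c in species:
            subs = [s for s in checklist.children_of(r.taxon_id)
                    if s.rank is Rank.SUBSPECIES]
            if not subs or any(s.taxon_id not in by_id
                               or by_id[s.taxon_id].concept is None
                               for s in subs):
                continue
            sub_ids = [by_id[s.taxon_id].concept for s in subs]
            ok = False
            for weights in tables:
                if weights is None or c not in weights \
                        or any(sc not in weights for sc in sub_ids):
                    continue
                if sum((weights[sc] for sc in sub_ids), Fraction(0)) == weights[c]:
                    ok = True
                    break
            if not ok:
                found.append(Violation(
                    3, (r.taxon_id,),
                    f"subspecies weights of {r.scientific_name} do not sum to "
                    f"the species weight in any variant"))

        # rule 5 -- same-rank concepts never share a branch
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                (ra, ca), (rb, cb) = pairs[i], pairs[j]
                if ra.rank is not rb.rank or ca == cb:
                    continue
                for v in ts.variants:
                    if ca in v and cb in v and (v.is_ancestor(ca, cb)
                                                or v.is_ancestor(cb, ca)):
                        found.append(Violation(
                            5, tuple(sorted((ca, cb))),
                            f"records {ra.taxon_id} and {rb.taxon_id} "
                            f"({ra.rank.value}) map along one branch"))
                        break

        # rule 6 -- checklist parent links mirror tree ancestry
        for r, c in pairs:
            pid = r.parent_taxon_id
            if pid is None or pid not in mapped_ids:
                continue
            pc = mapped_ids[pid]
            if c == pc:
                siblings = [s for s in checklist.children_of(pid)
                            if s.rank is Rank.SUBSPECIES]
                if r.rank is Rank.SUBSPECIES and len(siblings) == 1:
                    continue  # monotypic nominal alias
                found.append(Violation(
                    6, (r.taxon_id, pid),
                    f"records {r.taxon_id} and {pid} share concept {c} outside "
                    f"the monotypic-alias case"))
                continue
            if not any(pc in v and c in v and v.is_ancestor(pc, c)
                       for v in ts.variants):
                found.append(Violation(
                    6, (r.taxon_id, pid),
                    f"concept {c} of record {r.taxon_id} is not a descendant "
                    f"of its parent's concept {pc}"))

    # rule 2 -- the attained total must be attainable by only one assignment.
    # Re-run the candidate enumeration; flag records the mapping claims as
    # uniquely mapped although several full solutions assign them differently.
    try:
        cands_all = resolve_candidates(checklist, store)
        cands = {tid: tuple(sorted(c for c in cs
                                   if store.treeset_for(c) is not None))
                 for tid, cs in cands_all.items()}
        in_tree = [r for r in checklist.records if cands[r.taxon_id]]
        for group in _search_groups(in_tree, cands, store):
            solutions = _enumerate_group(group, cands, store, checklist, cap)
            if len(solutions) <= 1:
                continue
            for r in group["records"]:
                entry = by_id.get(r.taxon_id)
                if entry is None or entry.status is not MappingStatus.MAPPED:
                    continue
                ids = sorted({s.mapping[r.taxon_id] for s in solutions})
                if len(ids) > 1:
                    found.append(Violation(
                        2, (r.taxon_id,),
                        f"record {r.taxon_id} is marked mapped but "
                        f"{len(solutions)} valid assignments exist "
                        f"({', '.join(ids)})"))
    except CombinationBudgetError:
        pass  # uniqueness not checkable at this size; rules 1 and 3-6 stand

    return ValidationReport(found)
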