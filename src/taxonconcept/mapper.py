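"""Mapping checklist names onto concept identifiers.

A published checklist is a full snapshot of name usages (partial revisions
are treated as if the whole list had been re-published with the changes
applied).  Mapping proceeds in two steps: names are resolved to candidate
concept IDs through the store's labels and synonym table, then a combinatorial
search looks, independently per concept tree, for assignments of one candidate
per record whose fractional weights sum exactly to the (scope-adjusted) total
without breaking the branch and descendant rules.  Exactly one surviving
assignment means the records are mapped; several mean genuine ambiguity, which
is reported, never resolved by heuristics; none means a conflict (a new
concept, or a mis-constructed tree).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Union

from .errors import ChecklistError, CombinationBudgetError, EmptyScopeError
from .store import (ConceptStore, Kind, Rank, TreeSet, TreeVariant,
                    canonicalize_name)
from .weights import compute_weights, scoped_weights

__all__ = [
    "TaxonRecord",
    "Checklist",
    "GLOBAL_SCOPE",
    "MappingStatus",
    "MappingEntry",
    "MappingResult",
    "resolve_candidates",
    "solve_assignment",
    "enumerate_valid_arrangements",
    "diff_checklists",
    "Change",
    "ChangeSet",
    "candidates_from_diff",
    "DEFAULT_COMBINATION_CAP",
]

GLOBAL_SCOPE = "global"
DEFAULT_COMBINATION_CAP = 10 ** 6

Scope = Union[str, frozenset]


@dataclass(frozen=True)
class TaxonRecord:
    """One row of a checklist: a local key, a name usage and its rank, plus an
    optional parent link (subspecies reference their species row)."""

    taxon_id: str
    scientific_name: str
    rank: Rank
    parent_taxon_id: Optional[str] = None
    vernacular: Optional[str] = None

    @property
    def canonical_name(self) -> str:
        return canonicalize_name(self.scientific_name)


@dataclass
class Checklist:
    """A versioned full snapshot of published name usages.

    ``scope`` is either :data:`GLOBAL_SCOPE` or a frozenset of terminal
    concept IDs covered by the authority (regional checklists).
    """

    authority: str
    version_label: str
    year: int
    records: list[TaxonRecord]
    scope: Scope = GLOBAL_SCOPE

    def __post_init__(self):
        seen: set[str] = set()
        for r in self.records:
            if r.taxon_id in seen:
                raise ChecklistError(f"duplicate taxonID: {r.taxon_id}")
            seen.add(r.taxon_id)
        by_id = {r.taxon_id: r for r in self.records}
        for r in self.records:
            if r.parent_taxon_id is not None:
                parent = by_id.get(r.parent_taxon_id)
                if parent is None:
                    raise ChecklistError(
                        f"record {r.taxon_id} references missing parent "
                        f"{r.parent_taxon_id}")
            elif r.rank is Rank.SUBSPECIES:
                raise ChecklistError(
                    f"subspecies record {r.taxon_id} has no parent species")
        if self.scope != GLOBAL_SCOPE:
            self.scope = frozenset(self.scope)
            if not self.scope:
                raise EmptyScopeError("checklist scope is empty")

    def record(self, taxon_id: str) -> TaxonRecord:
        for r in self.records:
            if r.taxon_id == taxon_id:
                return r
        raise KeyError(taxon_id)

    def children_of(self, taxon_id: str) -> list[TaxonRecord]:
        return [r for r in self.records if r.parent_taxon_id == taxon_id]


class MappingStatus(str, Enum):
    MAPPED = "mapped"
    AMBIGUOUS = "ambiguous"
    UNMAPPED_NEW = "unmapped_new"
    CONFLICT = "conflict"


@dataclass
class MappingEntry:
    taxon_id: str
    scientific_name: str
    status: MappingStatus
    concept: Optional[str] = None
    candidates: tuple[str, ...] = ()
    variant: Optional[int] = None


@dataclass
class MappingResult:
    """Per-record mapping outcomes, in checklist order."""

    entries: list[MappingEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def by_id(self) -> dict[str, MappingEntry]:
        return {e.taxon_id: e for e in self.entries}

    def concept_of(self, taxon_id: str) -> Optional[str]:
        entry = self.by_id.get(taxon_id)
        return entry.concept if entry else None


# ---------------------------------------------------------------------------
# candidate resolution


def resolve_candidates(checklist: Checklist, store: ConceptStore
                       ) -> dict[str, frozenset[str]]:
    """Candidate concept IDs for every record, by exact canonical-name lookup
    against labels and synonyms.  An empty set marks a potential new concept."""
    return {r.taxon_id: store.lookup_name(r.scientific_name)
            for r in checklist.records}


# ---------------------------------------------------------------------------
# the combinatorial search


@dataclass(frozen=True)
class _Solution:
    assignment: tuple[tuple[str, str], ...]   # (taxon_id, concept id)
    variants: tuple[tuple[str, int], ...]     # (tree root, variant index)

    @property
    def mapping(self) -> dict[str, str]:
        return dict(self.assignment)

    @property
    def variant_by_root(self) -> dict[str, int]:
        return dict(self.variants)


def _variant_tables(ts: TreeSet, scope: Scope) -> list[Optional[dict[str, Fraction]]]:
    """Per-variant weight tables (scope-adjusted); ``None`` marks a variant
    rendered unusable because the scope misses it entirely."""
    tables: list[Optional[dict[str, Fraction]]] = []
    for v in ts.variants:
        if scope == GLOBAL_SCOPE:
            tables.append(compute_weights(v))
        else:
            eff = frozenset(scope) & v.leaf_set(v.root)
            tables.append(scoped_weights(v, eff) if eff else None)
    return tables


def _rule4_ok(records: list[TaxonRecord], mapping: Mapping[str, str]) -> bool:
    """Only one record per concept ID, except a monotypic species and its
    nominal subspecies (same ID via label aliasing)."""
    holders: dict[str, list[TaxonRecord]] = {}
    for r in records:
        holders.setdefault(mapping[r.taxon_id], []).append(r)
    for recs in holders.values():
        if len(recs) == 1:
            continue
        if len(recs) != 2:
            return False
        a, b = sorted(recs, key=lambda r: r.rank.value)  # species < subspecies
        if not (a.rank is Rank.SPECIES and b.rank is Rank.SUBSPECIES
                and b.parent_taxon_id == a.taxon_id):
            return False
    return True


def _check_root(records_r: list[TaxonRecord], mapping: Mapping[str, str],
                ts: TreeSet, tables, checklist: Checklist,
                in_group: frozenset[str]) -> Optional[int]:
    """First variant index of *ts* under which the assignment satisfies the
    sum (rules 1 and 3) and branch/descendant (rules 5 and 6) constraints, or
    ``None``."""
    for vi, weights in enumerate(tables):
        if weights is None:
            continue
        variant = ts.variants[vi]
        ids = {r.taxon_id: mapping[r.taxon_id] for r in records_r}
        if any(c not in weights for c in ids.values()):
            continue
        ok = True
        # rule 5: no two same-rank usages along one branch
        for ra, rb in itertools.combinations(records_r, 2):
            if ra.rank is not rb.rank:
                continue
            ca, cb = ids[ra.taxon_id], ids[rb.taxon_id]
            if ca == cb:
                continue
            if variant.is_ancestor(ca, cb) or variant.is_ancestor(cb, ca):
                ok = False
                break
        if not ok:
            continue
        # rule 1: species usages tile the (scope-adjusted) tree exactly
        species = [r for r in records_r if r.rank is Rank.SPECIES]
        if species:
            total = sum((weights[ids[r.taxon_id]] for r in species), Fraction(0))
            if total != 1:
                continue
        # rule 3: subspecies of a species sum to the species' own weight
        # (checked only when every subspecies row landed in this search group)
        for r in species:
            subs = [c for c in checklist.children_of(r.taxon_id)
                    if c.rank is Rank.SUBSPECIES]
            if not subs or any(c.taxon_id not in in_group for c in subs):
                continue
            sub_sum = sum((weights[mapping[c.taxon_id]] for c in subs), Fraction(0))
            if sub_sum != weights[ids[r.taxon_id]]:
                ok = False
                break
        if not ok:
            continue
        # rule 6: checklist parent links mirror tree ancestry
        for r in records_r:
            pid = r.parent_taxon_id
            if pid is None or pid not in mapping:
                continue
            child_c, parent_c = ids[r.taxon_id], mapping[pid]
            if child_c == parent_c:
                # monotypic alias: the nominal subspecies may share the
                # species' ID only when it is the sole subspecies row
                siblings = [c for c in checklist.children_of(pid)
                            if c.rank is Rank.SUBSPECIES]
                if not (r.rank is Rank.SUBSPECIES and len(siblings) == 1):
                    ok = False
                    break
            elif parent_c not in variant or not variant.is_ancestor(parent_c, child_c):
                ok = False
                break
        if ok:
            return vi
    return None


def _search_groups(records: list[TaxonRecord],
                   cands: Mapping[str, tuple[str, ...]],
                   store: ConceptStore):
    """Partition records into independent search groups.

    Two tree roots end up in one group when a record's candidates span both,
    or when a parent link connects records resolving into different trees.
    """
    up: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while up.setdefault(root, root) != root:
            root = up[root]
        while up[x] != root:  # path compression
            up[x], x = root, up[x]
        return root

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            up[max(ra, rb)] = min(ra, rb)

    rec_roots: dict[str, list[str]] = {}
    for r in records:
        roots = sorted({store.treeset_for(c).root for c in cands[r.taxon_id]})
        rec_roots[r.taxon_id] = roots
        for root in roots:
            find(root)
        for a, b in zip(roots, roots[1:]):
            union(a, b)
    for r in records:
        if r.parent_taxon_id in rec_roots and rec_roots[r.taxon_id] \
                and rec_roots[r.parent_taxon_id]:
            union(rec_roots[r.taxon_id][0], rec_roots[r.parent_taxon_id][0])

    groups: dict[str, dict] = {}
    for r in records:
        if not rec_roots[r.taxon_id]:
            continue
        key = find(rec_roots[r.taxon_id][0])
        g = groups.setdefault(key, {"records": [], "roots": set()})
        g["records"].append(r)
        g["roots"].update(rec_roots[r.taxon_id])
    for g in groups.values():
        g["roots"] = sorted(g["roots"])
    return [groups[k] for k in sorted(groups)]


def _enumerate_group(group: dict, cands: Mapping[str, tuple[str, ...]],
                     store: ConceptStore, checklist: Checklist,
                     cap: int) -> list[_Solution]:
    records: list[TaxonRecord] = group["records"]
    tids = [r.taxon_id for r in records]
    in_group = frozenset(tids)
    size = 1
    for t in tids:
        size *= len(cands[t])
        if size > cap:
            raise CombinationBudgetError(
                f"candidate combinations exceed cap ({cap}) for records {tids}")
    ts_by_root: dict[str, TreeSet] = {}
    tables_by_root: dict[str, list] = {}
    for root in group["roots"]:
        ts = store.treeset_for(root)
        assert ts is not None
        ts_by_root[root] = ts
        tables_by_root[root] = _variant_tables(ts, checklist.scope)

    solutions: list[_Solution] = []
    seen: set[tuple] = set()
    for combo in itertools.product(*(cands[t] for t in tids)):
        mapping = dict(zip(tids, combo))
        if not _rule4_ok(records, mapping):
            continue
        ok = True
        chosen: list[tuple[str, int]] = []
        for root in group["roots"]:
            ts = ts_by_root[root]
            records_r = [r for r in records if mapping[r.taxon_id] in ts.nodes]
            if not records_r:
                continue
            vi = _check_root(records_r, mapping, ts, tables_by_root[root],
                             checklist, in_group)
            if vi is None:
                ok = False
                break
            chosen.append((root, vi))
        if not ok:
            continue
        key = tuple(sorted(mapping.items()))
        if key in seen:
            continue  # same ID assignment reachable through several variants
        seen.add(key)
        solutions.append(_Solution(key, tuple(chosen)))
    return solutions


def solve_assignment(checklist: Checklist,
                     candidates: Mapping[str, Iterable[str]],
                     store: ConceptStore, *,
                     cap: int = DEFAULT_COMBINATION_CAP,
                     overrides: Optional[Mapping[str, str]] = None
                     ) -> MappingResult:
    """Search for the unique candidate assignment whose weights sum correctly.

    *overrides* forces selected records to a given concept (curator input for
    genuinely ambiguous cases); an override simply replaces the record's
    candidate set.
    """
    overrides = dict(overrides or {})
    cands: dict[str, tuple[str, ...]] = {}
    raw: dict[str, tuple[str, ...]] = {}
    for r in checklist.records:
        cs = frozenset(candidates.get(r.taxon_id, ()))
        if r.taxon_id in overrides:
            cs = frozenset({overrides[r.taxon_id]})
        raw[r.taxon_id] = tuple(sorted(cs))
        cands[r.taxon_id] = tuple(
            sorted(c for c in cs if store.treeset_for(c) is not None))

    entries: dict[str, MappingEntry] = {}
    in_tree_records = [r for r in checklist.records if cands[r.taxon_id]]
    for r in checklist.records:
        if not cands[r.taxon_id]:
            entries[r.taxon_id] = MappingEntry(
                r.taxon_id, r.scientific_name, MappingStatus.UNMAPPED_NEW,
                candidates=raw[r.taxon_id])

    for group in _search_groups(in_tree_records, cands, store):
        solutions = _enumerate_group(group, cands, store, checklist, cap)
        records: list[TaxonRecord] = group["records"]
        if not solutions:
            for r in records:
                entries[r.taxon_id] = MappingEntry(
                    r.taxon_id, r.scientific_name, MappingStatus.CONFLICT,
                    candidates=cands[r.taxon_id])
            continue
        for r in records:
            ids = sorted({s.mapping[r.taxon_id] for s in solutions})
            if len(ids) == 1:
                concept = ids[0]
                root = store.treeset_for(concept).root
                variant = solutions[0].variant_by_root.get(root)
                entries[r.taxon_id] = MappingEntry(
                    r.taxon_id, r.scientific_name, MappingStatus.MAPPED,
                    concept=concept, candidates=cands[r.taxon_id],
                    variant=variant)
            else:
                entries[r.taxon_id] = MappingEntry(
                    r.taxon_id, r.scientific_name, MappingStatus.AMBIGUOUS,
                    candidates=tuple(ids))
    return MappingResult([entries[r.taxon_id] for r in checklist.records])


# ---------------------------------------------------------------------------
# arrangement enumeration


_USABLE_KINDS = {
    Rank.SPECIES: {Kind.SPECIES},
    Rank.SUBSPECIES: {Kind.SUBSPECIES},
    Rank.OTHER: {Kind.GROUP, Kind.OTHER},
}


def enumerate_valid_arrangements(treeset: TreeSet, store: ConceptStore,
                                 rank: Rank = Rank.SPECIES
                                 ) -> list[frozenset[str]]:
    """All sets of rank-usable concepts whose weights sum exactly to 1 in at
    least one variant, with no ancestor-descendant pair; deduplicated across
    variants, in deterministic order."""
    usable = {n for n in treeset.nodes
              if store.concepts[n].kind in _USABLE_KINDS[Rank(rank)]}

    def arrangements(variant: TreeVariant, node: str) -> list[frozenset[str]]:
        opts: list[frozenset[str]] = []
        if node in usable:
            opts.append(frozenset({node}))
        children = sorted(variant.children(node))
        if children:
            per_child = [arrangements(variant, c) for c in children]
            if all(per_child):
                for combo in itertools.product(*per_child):
                    opts.append(frozenset().union(*combo))
        return opts

    out: set[frozenset[str]] = set()
    for v in treeset.variants:
        out.update(arrangements(v, v.root))
    return sorted(out, key=lambda s: (len(s), sorted(s)))


# ---------------------------------------------------------------------------
# diffing checklist versions


class ChangeKind(str, Enum):
    UNCHANGED = "unchanged"
    RENAMED = "renamed"
    ADDED = "added"
    REMOVED = "removed"


@dataclass(frozen=True)
class Change:
    kind: ChangeKind
    taxon_id: Optional[str] = None        # in the new checklist
    old_taxon_id: Optional[str] = None    # in the old checklist
    concept: Optional[str] = None
    old_name: Optional[str] = None
    new_name: Optional[str] = None


@dataclass
class ChangeSet:
    unchanged: list[Change] = field(default_factory=list)
    renamed: list[Change] = field(default_factory=list)
    added: list[Change] = field(default_factory=list)
    removed: list[Change] = field(default_factory=list)

    @property
    def changes(self) -> list[Change]:
        """Actual differences; empty for identical checklists."""
        return self.renamed + self.added + self.removed


def _epithets(canonical: str) -> tuple[str, ...]:
    return tuple(canonical.split()[1:])


def diff_checklists(old: Checklist, old_mapping: MappingResult,
                    new: Checklist, store: Optional[ConceptStore] = None
                    ) -> ChangeSet:
    """Classify each record of *new* against the already-mapped *old* version.

    A record with the same canonical name and rank is unchanged.  A record
    whose name differs only in genus placement or a gender emendation of the
    epithet -- detected by epithet identity, or through the synonym table when
    a *store* is given -- is a rename: the concept keeps its identifier.
    Everything else is an addition; old records never matched are removals.
    """
    concept_of = {e.taxon_id: e.concept for e in old_mapping
                  if e.concept is not None}
    old_free: dict[tuple[str, Rank], list[TaxonRecord]] = {}
    for r in old.records:
        old_free.setdefault((r.canonical_name, r.rank), []).append(r)

    cs = ChangeSet()
    matched_old: set[str] = set()
    pending: list[TaxonRecord] = []
    for r in new.records:
        bucket = old_free.get((r.canonical_name, r.rank))
        if bucket:
            o = bucket.pop(0)
            matched_old.add(o.taxon_id)
            cs.unchanged.append(Change(
                ChangeKind.UNCHANGED, r.taxon_id, o.taxon_id,
                concept_of.get(o.taxon_id), o.scientific_name,
                r.scientific_name))
        else:
            pending.append(r)

    leftovers = [o for o in old.records if o.taxon_id not in matched_old]
    for r in pending:
        hit = None
        if store is not None:
            named = store.lookup_name(r.scientific_name)
            for o in leftovers:
                if o.rank is r.rank and concept_of.get(o.taxon_id) in named:
                    hit = o
                    break
        if hit is None:
            for o in leftovers:
                if o.rank is r.rank and \
                        _epithets(o.canonical_name) == _epithets(r.canonical_name):
                    hit = o
                    break
        if hit is not None:
            leftovers.remove(hit)
            matched_old.add(hit.taxon_id)
            cs.renamed.append(Change(
                ChangeKind.RENAMED, r.taxon_id, hit.taxon_id,
                concept_of.get(hit.taxon_id), hit.scientific_name,
                r.scientific_name))
        else:
            cs.added.append(Change(ChangeKind.ADDED, r.taxon_id,
                                   new_name=r.scientific_name))
    for o in leftovers:
        cs.removed.append(Change(ChangeKind.REMOVED, old_taxon_id=o.taxon_id,
                                 concept=concept_of.get(o.taxon_id),
                                 old_name=o.scientific_name))
    return cs


def candidates_from_diff(changes: ChangeSet, new: Checklist,
                         store: ConceptStore) -> dict[str, frozenset[str]]:
    """Candidate sets narrowed by a diff: unchanged and renamed records keep
    their established concept; additions fall back to name lookup."""
    narrowed = resolve_candidates(new, store)
    for ch in changes.unchanged + changes.renamed:
        if ch.taxon_id is not None and ch.concept is not None:
            narrowed[ch.taxon_id] = frozenset({ch.concept})
    return narrowed
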