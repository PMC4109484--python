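"""Worked fixtures and simulated checklist histories with known ground truth.

Three classic concept-management situations ship as fixtures:

* ``vireo`` -- the Solitary Vireo complex: one root concept (*Vireo
  solitarius* sensu lato) split into three species, each with subspecies, and
  the nominal *plumbeus* subspecies further resolved into *jacksoni* and the
  nominal-excluding-*jacksoni* remainder.  A single tree covers all of it.
* ``pterodroma`` -- the *Pterodroma arminjoniana* superspecies with three
  terminal concepts (a, b, c) and two contradictory arrangements: *heraldica*
  with or without *atrata*.
* ``poicephalus`` -- the Cape/brown-necked parrot problem: the subspecies
  *suahelicus* placed alternately inside *Poicephalus robustus* or
  *Poicephalus fuscicollis*, creating two distinct species concepts for each
  binomial; a checklist giving only the two species names is genuinely
  ambiguous.

The simulator grows a random store through seeded revision histories (splits,
lumps, renames, elevations, subspecies reassignments) and emits each version
as a full-snapshot checklist with its true record-to-concept mapping, so the
mapper and validator can be exercised against known answers without any
external data.
"""

from __future__ import annotations

import copy
import itertools
import random
from dataclasses import dataclass, field

from .edits import elevate, merge_roots, reassign, split_terminal
from .errors import TaxonConceptError
from .mapper import (Checklist, MappingEntry, MappingResult, MappingStatus,
                     TaxonRecord)
from .store import ConceptStore, Kind, Rank, TreeSet, TreeVariant

__all__ = ["Fixture", "build_fixture", "FIXTURE_NAMES",
           "SimulationParams", "SimulatedHistory", "simulate_history"]

FIXTURE_NAMES = ("vireo", "pterodroma", "poicephalus")

_FIXTURE_SEEDS = {"vireo": 101, "pterodroma": 102, "poicephalus": 103}


@dataclass
class Fixture:
    store: ConceptStore
    checklists: dict[str, Checklist]
    key_ids: dict[str, str]


def build_fixture(name: str, seed: int | None = None) -> Fixture:
    """Build one of the packaged fixtures; identifiers are drawn from a seeded
    generator (per-fixture default seed), the structure never varies."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise TaxonConceptError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
    rng = random.Random(_FIXTURE_SEEDS[name] if seed is None else seed)
    return builder(rng)


def _new(store: ConceptStore, rng, kind: Kind) -> str:
    cid = store.new_id(rng)
    store.add_concept(cid, kind)
    return cid


def _vireo(rng) -> Fixture:
    store = ConceptStore()
    keys = {}
    for key, kind in [
        ("vireo_sl", Kind.SPECIES), ("vireo_ss", Kind.SPECIES),
        ("cassinii", Kind.SPECIES), ("plumbeus", Kind.SPECIES),
        ("ss_nominate", Kind.SUBSPECIES), ("alticola", Kind.SUBSPECIES),
        ("cassinii_nominate", Kind.SUBSPECIES), ("lucasanus", Kind.SUBSPECIES),
        ("plumbeus_nominate", Kind.SUBSPECIES), ("pinicolus", Kind.SUBSPECIES),
        ("repetens", Kind.SUBSPECIES), ("montanus", Kind.SUBSPECIES),
        ("notius", Kind.SUBSPECIES),
        ("plumbeus_excl_jacksoni", Kind.SUBSPECIES),
        ("jacksoni", Kind.SUBSPECIES),
    ]:
        keys[key] = _new(store, rng, kind)
    k = keys
    store.add_treeset(TreeSet(k["vireo_sl"], [TreeVariant({
        k["vireo_sl"]: {k["vireo_ss"], k["cassinii"], k["plumbeus"]},
        k["vireo_ss"]: {k["ss_nominate"], k["alticola"]},
        k["cassinii"]: {k["cassinii_nominate"], k["lucasanus"]},
        k["plumbeus"]: {k["plumbeus_nominate"], k["pinicolus"], k["repetens"],
                        k["montanus"], k["notius"]},
        k["plumbeus_nominate"]: {k["plumbeus_excl_jacksoni"], k["jacksoni"]},
    })]))
    for key, name, rank in [
        ("vireo_sl", "Vireo solitarius", Rank.SPECIES),
        ("vireo_ss", "Vireo solitarius", Rank.SPECIES),
        ("cassinii", "Vireo cassinii", Rank.SPECIES),
        ("plumbeus", "Vireo plumbeus", Rank.SPECIES),
        ("ss_nominate", "Vireo solitarius solitarius", Rank.SUBSPECIES),
        ("alticola", "Vireo solitarius alticola", Rank.SUBSPECIES),
        ("cassinii_nominate", "Vireo cassinii cassinii", Rank.SUBSPECIES),
        ("lucasanus", "Vireo cassinii lucasanus", Rank.SUBSPECIES),
        ("plumbeus_nominate", "Vireo plumbeus plumbeus", Rank.SUBSPECIES),
        ("pinicolus", "Vireo plumbeus pinicolus", Rank.SUBSPECIES),
        ("repetens", "Vireo plumbeus repetens", Rank.SUBSPECIES),
        ("montanus", "Vireo plumbeus montanus", Rank.SUBSPECIES),
        ("notius", "Vireo plumbeus notius", Rank.SUBSPECIES),
        ("plumbeus_excl_jacksoni", "Vireo plumbeus plumbeus", Rank.SUBSPECIES),
        ("jacksoni", "Vireo plumbeus jacksoni", Rank.SUBSPECIES),
    ]:
        store.add_name(keys[key], name, rank)
    # Trinomials as used while everything sat inside one species (concept
    # synonyms created by the later genus-internal transfers).
    for key, old in [
        ("cassinii_nominate", "Vireo solitarius cassinii"),
        ("lucasanus", "Vireo solitarius lucasanus"),
        ("plumbeus_nominate", "Vireo solitarius plumbeus"),
        ("pinicolus", "Vireo solitarius pinicolus"),
        ("repetens", "Vireo solitarius repetens"),
        ("montanus", "Vireo solitarius montanus"),
        ("notius", "Vireo solitarius notius"),
    ]:
        store.add_synonym(old, keys[key])

    def rec(tid, name, rank, parent=None):
        return TaxonRecord(tid, name, rank, parent)

    lumped = Checklist("AOU", "6th edition", 1983, [
        rec("s1", "Vireo solitarius", Rank.SPECIES),
        rec("s1.1", "Vireo solitarius solitarius", Rank.SUBSPECIES, "s1"),
        rec("s1.2", "Vireo solitarius alticola", Rank.SUBSPECIES, "s1"),
        rec("s1.3", "Vireo solitarius cassinii", Rank.SUBSPECIES, "s1"),
        rec("s1.4", "Vireo solitarius lucasanus", Rank.SUBSPECIES, "s1"),
        rec("s1.5", "Vireo solitarius plumbeus", Rank.SUBSPECIES, "s1"),
        rec("s1.6", "Vireo solitarius pinicolus", Rank.SUBSPECIES, "s1"),
        rec("s1.7", "Vireo solitarius repetens", Rank.SUBSPECIES, "s1"),
        rec("s1.8", "Vireo solitarius montanus", Rank.SUBSPECIES, "s1"),
        rec("s1.9", "Vireo solitarius notius", Rank.SUBSPECIES, "s1"),
    ])
    split = Checklist("AOU", "41st supplement", 1997, [
        rec("s1", "Vireo solitarius", Rank.SPECIES),
        rec("s1.1", "Vireo solitarius solitarius", Rank.SUBSPECIES, "s1"),
        rec("s1.2", "Vireo solitarius alticola", Rank.SUBSPECIES, "s1"),
        rec("s2", "Vireo cassinii", Rank.SPECIES),
        rec("s2.1", "Vireo cassinii cassinii", Rank.SUBSPECIES, "s2"),
        rec("s2.2", "Vireo cassinii lucasanus", Rank.SUBSPECIES, "s2"),
        rec("s3", "Vireo plumbeus", Rank.SPECIES),
        rec("s3.1", "Vireo plumbeus plumbeus", Rank.SUBSPECIES, "s3"),
        rec("s3.2", "Vireo plumbeus pinicolus", Rank.SUBSPECIES, "s3"),
        rec("s3.3", "Vireo plumbeus repetens", Rank.SUBSPECIES, "s3"),
        rec("s3.4", "Vireo plumbeus montanus", Rank.SUBSPECIES, "s3"),
        rec("s3.5", "Vireo plumbeus notius", Rank.SUBSPECIES, "s3"),
    ])
    species_only = Checklist("NewAuthority", "1.0", 2001, [
        rec("s1", "Vireo solitarius", Rank.SPECIES),
    ])
    return Fixture(store, {"lumped": lumped, "split": split,
                           "species_only": species_only}, keys)


def _pterodroma(rng) -> Fixture:
    store = ConceptStore()
    keys = {key: _new(store, rng, Kind.SPECIES)
            for key in ("root", "ab", "ac", "a", "b", "c")}
    k = keys
    variant_a = TreeVariant({k["root"]: {k["ab"], k["c"]},
                             k["ab"]: {k["a"], k["b"]}})
    variant_b = TreeVariant({k["root"]: {k["ac"], k["b"]},
                             k["ac"]: {k["a"], k["c"]}})
    store.add_treeset(TreeSet(k["root"], [variant_a, variant_b]))
    for key, name in [
        ("root", "Pterodroma arminjoniana"),   # the superspecies, s.l.
        ("ab", "Pterodroma arminjoniana"),     # including heraldica
        ("ac", "Pterodroma heraldica"),        # including atrata
        ("a", "Pterodroma heraldica"),
        ("b", "Pterodroma arminjoniana"),
        ("c", "Pterodroma atrata"),
    ]:
        store.add_name(keys[key], name, Rank.SPECIES)

    three = Checklist("GlobalList", "v3", 2010, [
        TaxonRecord("p1", "Pterodroma arminjoniana", Rank.SPECIES),
        TaxonRecord("p2", "Pterodroma atrata", Rank.SPECIES),
        TaxonRecord("p3", "Pterodroma heraldica", Rank.SPECIES),
    ])
    heraldica_lump = Checklist("GlobalList", "v2", 2004, [
        TaxonRecord("p1", "Pterodroma arminjoniana", Rank.SPECIES),
        TaxonRecord("p2", "Pterodroma heraldica", Rank.SPECIES),
    ])
    return Fixture(store, {"three_species": three,
                           "heraldica_lumped": heraldica_lump}, keys)


def _poicephalus(rng) -> Fixture:
    store = ConceptStore()
    keys = {}
    for key, kind in [
        ("root", Kind.GROUP),
        ("robustus_sl", Kind.SPECIES), ("fuscicollis_sl", Kind.SPECIES),
        ("robustus_nominate", Kind.SPECIES),       # also used as a subspecies
        ("fuscicollis_west", Kind.SPECIES),        # monotypic in one treatment
        ("suahelicus", Kind.SUBSPECIES),
    ]:
        keys[key] = _new(store, rng, kind)
    k = keys
    variant1 = TreeVariant({   # robustus = nominate + suahelicus
        k["root"]: {k["robustus_sl"], k["fuscicollis_west"]},
        k["robustus_sl"]: {k["robustus_nominate"], k["suahelicus"]},
    })
    variant2 = TreeVariant({   # fuscicollis = suahelicus + western birds
        k["root"]: {k["robustus_nominate"], k["fuscicollis_sl"]},
        k["fuscicollis_sl"]: {k["suahelicus"], k["fuscicollis_west"]},
    })
    store.add_treeset(TreeSet(k["root"], [variant1, variant2]))
    for key, name, rank in [
        ("robustus_sl", "Poicephalus robustus", Rank.SPECIES),
        ("robustus_nominate", "Poicephalus robustus", Rank.SPECIES),
        ("robustus_nominate", "Poicephalus robustus robustus", Rank.SUBSPECIES),
        ("fuscicollis_sl", "Poicephalus fuscicollis", Rank.SPECIES),
        ("fuscicollis_west", "Poicephalus fuscicollis", Rank.SPECIES),
        ("fuscicollis_west", "Poicephalus fuscicollis fuscicollis",
         Rank.SUBSPECIES),
        ("suahelicus", "Poicephalus robustus suahelicus", Rank.SUBSPECIES),
        ("suahelicus", "Poicephalus fuscicollis suahelicus", Rank.SUBSPECIES),
    ]:
        store.add_name(keys[key], name, rank)

    # Deliberately no subspecies rows: with two bare binomials either
    # published arrangement fits, so the mapping must come back ambiguous.
    two_species = Checklist("ParrotList", "v1", 2012, [
        TaxonRecord("q1", "Poicephalus robustus", Rank.SPECIES),
        TaxonRecord("q2", "Poicephalus fuscicollis", Rank.SPECIES),
    ])
    with_subspecies = Checklist("ParrotList", "v2", 2016, [
        TaxonRecord("q1", "Poicephalus robustus", Rank.SPECIES),
        TaxonRecord("q1.1", "Poicephalus robustus robustus", Rank.SUBSPECIES,
                    "q1"),
        TaxonRecord("q1.2", "Poicephalus robustus suahelicus", Rank.SUBSPECIES,
                    "q1"),
        TaxonRecord("q2", "Poicephalus fuscicollis", Rank.SPECIES),
    ])
    return Fixture(store, {"two_species": two_species,
                           "with_subspecies": with_subspecies}, keys)


_BUILDERS = {"vireo": _vireo, "pterodroma": _pterodroma,
             "poicephalus": _poicephalus}


# ---------------------------------------------------------------------------
# simulated checklist histories


@dataclass
class SimulationParams:
    """Conditions for a simulated revision history.

    Event probabilities are per recognized species per version.  With
    ``homonym_rate`` zero, the only name reuse across concepts is the
    structurally unavoidable kind (a split's remainder keeps its trinomial,
    an elevated nominate subspecies takes the old binomial, a lump keeps the
    senior name); a positive rate additionally recycles retired names onto
    unrelated concepts.
    """

    n_species: int = 8
    subspecies_range: tuple[int, int] = (1, 4)
    n_versions: int = 5
    p_split: float = 0.15
    p_lump: float = 0.05
    p_rename: float = 0.15
    p_elevate: float = 0.10
    p_reassign: float = 0.05
    homonym_rate: float = 0.0
    include_subspecies: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_versions < 1:
            raise ValueError("n_versions must be >= 1")
        lo, hi = self.subspecies_range
        if not (1 <= lo <= hi):
            raise ValueError("subspecies_range must be 1 <= lo <= hi")
        probs = (self.p_split, self.p_lump, self.p_rename, self.p_elevate,
                 self.p_reassign, self.homonym_rate)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("event probabilities must lie in [0, 1]")
        if sum(probs[:5]) > 1.0:
            raise ValueError("per-species event probabilities must sum to <= 1")


@dataclass
class SimulatedHistory:
    """A revision history: the final store, one full-snapshot checklist and
    true mapping per version, and the store as it stood when each version was
    published (the state a curator would map that version against)."""

    store: ConceptStore
    checklists: list[Checklist]
    truths: list[MappingResult]
    stores: list[ConceptStore] = field(default_factory=list)


_SYLLABLES = ("ba", "ce", "do", "fi", "ga", "hu", "li", "mo", "ne", "pa",
              "ru", "sa", "ti", "vo", "xa", "ze", "bra", "cor", "dul", "fer",
              "gal", "hir", "lon", "mar", "nig", "pal", "ros", "sil", "tor",
              "ven")
_SUFFIXES = ("us", "a", "um", "is", "ii", "ensis", "oides")


class _Namer:
    """Latin-looking unique genus and epithet strings."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def _word(self) -> str:
        n = self.rng.randint(2, 3)
        return "".join(self.rng.choice(_SYLLABLES) for _ in range(n)) \
            + self.rng.choice(_SUFFIXES)

    def epithet(self) -> str:
        while True:
            w = self._word()
            if w not in self.used:
                self.used.add(w)
                return w

    def genus(self) -> str:
        while True:
            w = self._word().capitalize()
            if w not in self.used:
                self.used.add(w)
                return w


class _History:
    """Mutable simulation state: the store, the authority's currently
    recognized species, and the working names of every concept."""

    def __init__(self, params: SimulationParams):
        params.validate()
        self.params = params
        self.rng = random.Random(params.seed)
        self.namer = _Namer(self.rng)
        self.store = ConceptStore()
        self.recognized: set[str] = set()
        self.binomial: dict[str, str] = {}
        self.epithet: dict[str, str] = {}
        self.retired: list[str] = []

    # -- construction ------------------------------------------------------

    def build_base(self) -> None:
        p, rng, store = self.params, self.rng, self.store
        for _ in range(p.n_species):
            genus, ep = self.namer.genus(), self.namer.epithet()
            sid = store.new_id(rng)
            store.add_concept(sid, Kind.SPECIES)
            self.binomial[sid] = f"{genus} {ep}"
            self.epithet[sid] = ep
            store.add_name(sid, self.binomial[sid], Rank.SPECIES)
            n_subs = rng.randint(*p.subspecies_range)
            if n_subs == 1:
                # monotypic: one concept, binomial and nominal trinomial alias
                store.add_name(sid, f"{genus} {ep} {ep}", Rank.SUBSPECIES)
                store.add_treeset(TreeSet(sid, [TreeVariant({},
                                                            extra_nodes=(sid,))]))
            else:
                leaves = []
                for j in range(n_subs):
                    lid = store.new_id(rng)
                    store.add_concept(lid, Kind.SUBSPECIES)
                    self.epithet[lid] = ep if j == 0 else self.namer.epithet()
                    leaves.append(lid)
                store.add_treeset(TreeSet(sid, [TreeVariant({sid: leaves})]))
            self.recognized.add(sid)

    # -- helpers -----------------------------------------------------------

    def _in_use(self) -> set[str]:
        return {self.binomial[c] for c in self.recognized}

    def _maybe_reused_epithet(self) -> str:
        if self.rng.random() < self.params.homonym_rate and self.epithet:
            pool = sorted(set(self.epithet.values()))
            return self.rng.choice(pool)
        return self.namer.epithet()

    def _genus(self, concept: str) -> str:
        return self.binomial[concept].split()[0]

    def _covering_variant(self, ts) -> int | None:
        """Most recent variant containing every recognized species of *ts* --
        the arrangement the authority currently works from."""
        rec = [c for c in sorted(self.recognized)
               if self.store.treeset_for(c) is ts]
        for i in range(len(ts.variants) - 1, -1, -1):
            if all(c in ts.variants[i] for c in rec):
                return i
        return None

    # -- events ------------------------------------------------------------

    def ev_split(self, sp: str) -> None:
        leaves = sorted(self.store.leaf_set(sp))
        leaf = self.rng.choice(leaves)
        c1, c2 = split_terminal(leaf, 2, self.store, self.rng)
        # the remainder concept keeps the old trinomial (concept homonym)
        self.epithet[c1] = self.epithet.get(leaf, self.epithet.get(sp, ""))
        self.epithet[c2] = self._maybe_reused_epithet()

    def ev_rename(self, sp: str) -> None:
        old = self.binomial[sp]
        reusable = [n for n in sorted(set(self.retired))
                    if n not in self._in_use()]
        if self.rng.random() < self.params.homonym_rate and reusable:
            new = self.rng.choice(reusable)
        else:
            new = f"{self.namer.genus()} {self.epithet[sp]}"  # genus transfer
        self.binomial[sp] = new
        self.store.add_name(sp, new, Rank.SPECIES)
        self.retired.append(old)

    def ev_elevate(self, sp: str) -> None:
        ts = self.store.treeset_for(sp)
        vi = self._covering_variant(ts)
        if vi is None:
            return
        children = sorted(ts.variants[vi].children(sp))
        if len(children) < 2:
            return
        genus = self._genus(sp)
        self.recognized.discard(sp)
        for c in children:
            name = f"{genus} {self.epithet[c]}"
            elevate(c, name, self.store)
            self.binomial[c] = name
            self.recognized.add(c)

    def ev_lump(self, sp: str) -> None:
        own = self.store.treeset_for(sp)
        if own.root != sp:
            return
        partners = sorted(
            q for q in self.recognized
            if q != sp and self.store.treeset_for(q).root == q
            and self.store.treeset_for(q) is not own)
        if not partners:
            return
        partner = self.rng.choice(partners)
        new_root = merge_roots(sp, partner, self.store, self.rng,
                               kind=Kind.SPECIES)
        # the lump keeps the senior name: an inherent concept homonym
        self.binomial[new_root] = self.binomial[sp]
        self.epithet[new_root] = self.epithet[sp]
        self.store.add_name(new_root, self.binomial[new_root], Rank.SPECIES)
        self.recognized -= {sp, partner}
        self.recognized.add(new_root)
        self.retired.append(self.binomial[partner])

    def ev_reassign(self, sp: str) -> None:
        sp_leaves = self.store.leaf_set(sp)
        if len(sp_leaves) < 2:
            return
        own = self.store.treeset_for(sp)
        partners = []
        for q in sorted(self.recognized):
            if q == sp or self.store.leaf_set(q) & sp_leaves:
                continue
            ts_q = self.store.treeset_for(q)
            if ts_q is own and (sp == own.root or q == own.root):
                continue
            partners.append(q)
        if not partners:
            return
        partner = self.rng.choice(partners)
        moved = self.rng.choice(sorted(sp_leaves))
        if self.store.treeset_for(partner) is not own:
            merge_roots(own.root, self.store.treeset_for(partner).root,
                        self.store, self.rng)
        ts = self.store.treeset_for(sp)
        vi = self._covering_variant(ts)
        if vi is None or sp not in ts.variants[vi] \
                or partner not in ts.variants[vi]:
            return
        res = reassign({moved}, sp, partner, self.store, self.rng,
                       variant_index=vi)
        a_prime, b_prime = res["a_prime"], res["b_prime"]
        # A' keeps the recipient's name; B' keeps the donor's unless it
        # collapsed to a single pre-existing terminal
        self.binomial[a_prime] = self.binomial[partner]
        self.epithet[a_prime] = self.epithet[partner]
        self.store.add_name(a_prime, self.binomial[a_prime], Rank.SPECIES)
        if b_prime not in self.binomial:
            if b_prime in self.epithet:   # reused terminal, elevated
                self.binomial[b_prime] = \
                    f"{self._genus(sp)} {self.epithet[b_prime]}"
                self.retired.append(self.binomial[sp])
            else:
                self.binomial[b_prime] = self.binomial[sp]
                self.epithet[b_prime] = self.epithet[sp]
        self.store.add_name(b_prime, self.binomial[b_prime], Rank.SPECIES)
        self.recognized -= {sp, partner}
        self.recognized.update({a_prime, b_prime})

    def apply_events(self) -> None:
        p = self.params
        order = sorted(self.recognized, key=lambda c: (self.binomial[c], c))
        for sp in order:
            if sp not in self.recognized:
                continue  # consumed by an earlier lump/reassign this round
            u = self.rng.random()
            if u < p.p_split:
                self.ev_split(sp)
            elif u < p.p_split + p.p_lump:
                self.ev_lump(sp)
            elif u < p.p_split + p.p_lump + p.p_rename:
                self.ev_rename(sp)
            elif u < p.p_split + p.p_lump + p.p_rename + p.p_elevate:
                self.ev_elevate(sp)
            elif u < p.p_split + p.p_lump + p.p_rename + p.p_elevate \
                    + p.p_reassign:
                self.ev_reassign(sp)

    # -- emission ----------------------------------------------------------

    def emit(self, version_idx: int) -> tuple[Checklist, MappingResult]:
        records: list[TaxonRecord] = []
        truth: list[MappingEntry] = []
        counter = itertools.count(1)
        for sp in sorted(self.recognized, key=lambda c: (self.binomial[c], c)):
            name = self.binomial[sp]
            self.store.add_name(sp, name, Rank.SPECIES)
            sp_tid = f"t{next(counter)}"
            records.append(TaxonRecord(sp_tid, name, Rank.SPECIES))
            truth.append(MappingEntry(sp_tid, name, MappingStatus.MAPPED,
                                      concept=sp, candidates=(sp,)))
            leaves = self.store.leaf_set(sp)
            if not self.params.include_subspecies or len(leaves) < 2:
                continue
            for leaf in sorted(leaves, key=lambda l: (self.epithet[l], l)):
                tri = f"{name} {self.epithet[leaf]}"
                self.store.add_name(leaf, tri, Rank.SUBSPECIES)
                tid = f"t{next(counter)}"
                records.append(TaxonRecord(tid, tri, Rank.SUBSPECIES,
                                           parent_taxon_id=sp_tid))
                truth.append(MappingEntry(tid, tri, MappingStatus.MAPPED,
                                          concept=leaf, candidates=(leaf,)))
        checklist = Checklist("SimAuthority", f"v{version_idx + 1}",
                              2000 + version_idx, records)
        return checklist, MappingResult(truth)


def simulate_history(params: SimulationParams) -> SimulatedHistory:
    """Run a seeded revision history; reproducible bit-for-bit under a fixed
    seed.  Each version is a full-snapshot checklist plus its true mapping,
    together with a snapshot of the store at publication time."""
    hist = _History(params)
    hist.build_base()
    checklists: list[Checklist] = []
    truths: list[MappingResult] = []
    stores: list[ConceptStore] = []
    for v in range(params.n_versions):
        if v:
            hist.apply_events()
        checklist, truth = hist.emit(v)
        checklists.append(checklist)
        truths.append(truth)
        stores.append(copy.deepcopy(hist.store))
    return SimulatedHistory(hist.store, checklists, truths, stores)
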