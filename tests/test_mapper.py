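import random
from fractions import Fraction

import pytest

import taxonconcept as tc
from taxonconcept import (Checklist, ConceptStore, Kind, MappingStatus, Rank,
                          TaxonRecord, TreeSet, TreeVariant,
                          candidates_from_diff, compute_weights,
                          diff_checklists, enumerate_valid_arrangements,
                          resolve_candidates, solve_assignment)
from taxonconcept.edits import elevate

from helpers import brute_force_solutions, expected_statuses


def _solve(checklist, store, **kw):
    return solve_assignment(checklist, resolve_candidates(checklist, store),
                            store, **kw)


class TestResolveCandidates:
    def test_homonymous_binomial_yields_two_candidates(self, vireo):
        cands = resolve_candidates(vireo.checklists["species_only"],
                                   vireo.store)
        assert len(cands["s1"]) == 2

    def test_unknown_name_yields_empty_set_and_new_status(self, vireo):
        checklist = Checklist("X", "1", 2000, [
            TaxonRecord("n1", "Xenoglaux whoknows", Rank.SPECIES)])
        cands = resolve_candidates(checklist, vireo.store)
        assert cands["n1"] == frozenset()
        result = solve_assignment(checklist, cands, vireo.store)
        assert result.by_id["n1"].status is MappingStatus.UNMAPPED_NEW

    def test_parrot_names_are_doubly_ambiguous(self, poicephalus):
        cands = resolve_candidates(poicephalus.checklists["two_species"],
                                   poicephalus.store)
        assert len(cands["q1"]) == 2 and len(cands["q2"]) == 2


class TestSolveAssignment:
    def test_lone_binomial_maps_to_the_lumped_concept(self, vireo):
        result = _solve(vireo.checklists["species_only"], vireo.store)
        e = result.by_id["s1"]
        assert e.status is MappingStatus.MAPPED
        assert e.concept == vireo.key_ids["vireo_sl"]

    def test_three_way_revision_maps_to_sensu_stricto(self, vireo):
        result = _solve(vireo.checklists["split"], vireo.store)
        assert result.by_id["s1"].concept == vireo.key_ids["vireo_ss"]
        assert all(e.status is MappingStatus.MAPPED for e in result)
        # the homonymous nominal plumbeus trinomial resolves by weight sum
        assert result.by_id["s3.1"].concept == vireo.key_ids["plumbeus_nominate"]

    def test_lumped_checklist_with_subspecies(self, vireo):
        result = _solve(vireo.checklists["lumped"], vireo.store)
        assert result.by_id["s1"].concept == vireo.key_ids["vireo_sl"]
        assert all(e.status is MappingStatus.MAPPED for e in result)

    def test_underspecified_parrots_are_reported_ambiguous(self, poicephalus):
        result = _solve(poicephalus.checklists["two_species"],
                        poicephalus.store)
        for tid in ("q1", "q2"):
            e = result.by_id[tid]
            assert e.status is MappingStatus.AMBIGUOUS
            assert len(e.candidates) == 2

    def test_subspecies_rows_resolve_the_parrot_ambiguity(self, poicephalus):
        k = poicephalus.key_ids
        result = _solve(poicephalus.checklists["with_subspecies"],
                        poicephalus.store)
        assert result.by_id["q1"].concept == k["robustus_sl"]
        assert result.by_id["q2"].concept == k["fuscicollis_west"]

    def test_curator_override_settles_ambiguity(self, poicephalus):
        k = poicephalus.key_ids
        checklist = poicephalus.checklists["two_species"]
        result = _solve(checklist, poicephalus.store,
                        overrides={"q1": k["robustus_sl"]})
        assert result.by_id["q1"].concept == k["robustus_sl"]
        assert result.by_id["q2"].concept == k["fuscicollis_west"]

    def test_combination_cap_guards_blowup(self, poicephalus):
        with pytest.raises(tc.CombinationBudgetError):
            _solve(poicephalus.checklists["two_species"], poicephalus.store,
                   cap=3)

    def test_elevation_creates_a_third_homonym_with_the_expected_weights(
            self, vireo):
        store, k = vireo.store, vireo.key_ids
        elevate(k["ss_nominate"], "Vireo solitarius", store)
        elevate(k["alticola"], "Vireo alticola", store)
        ids = store.lookup_name("Vireo solitarius")
        assert ids == {k["vireo_sl"], k["vireo_ss"], k["ss_nominate"]}
        w = compute_weights(store.treesets[0].variants[0])
        assert sorted(w[c] for c in ids) == \
            [Fraction(1, 6), Fraction(1, 3), Fraction(1)]
        checklist = Checklist("X", "1", 2002, [
            TaxonRecord("a", "Vireo solitarius", Rank.SPECIES),
            TaxonRecord("b", "Vireo alticola", Rank.SPECIES),
            TaxonRecord("c", "Vireo cassinii", Rank.SPECIES),
            TaxonRecord("d", "Vireo plumbeus", Rank.SPECIES),
        ])
        result = _solve(checklist, store)
        assert result.by_id["a"].concept == k["ss_nominate"]
        assert result.by_id["b"].concept == k["alticola"]


class TestArrangementEnumeration:
    def test_vireo_has_two_species_level_options(self, vireo):
        arr = enumerate_valid_arrangements(vireo.store.treesets[0],
                                           vireo.store)
        k = vireo.key_ids
        assert arr == sorted([
            frozenset({k["vireo_sl"]}),
            frozenset({k["vireo_ss"], k["cassinii"], k["plumbeus"]}),
        ], key=lambda s: (len(s), sorted(s)))

    def test_petrels_have_four(self, pterodroma):
        arr = enumerate_valid_arrangements(pterodroma.store.treesets[0],
                                           pterodroma.store)
        k = pterodroma.key_ids
        assert len(arr) == 4
        assert frozenset({k["root"]}) in arr
        assert frozenset({k["ab"], k["c"]}) in arr
        assert frozenset({k["ac"], k["b"]}) in arr
        assert frozenset({k["a"], k["b"], k["c"]}) in arr

    def test_single_node_tree_has_one(self):
        store = ConceptStore()
        sp = store.new_id(random.Random(1))
        store.add_concept(sp, Kind.SPECIES)
        store.add_treeset(TreeSet(sp, [TreeVariant({}, extra_nodes=(sp,))]))
        assert enumerate_valid_arrangements(store.treesets[0], store) == \
            [frozenset({sp})]

    def test_every_arrangement_sums_to_one_in_some_variant(self, pterodroma):
        ts = pterodroma.store.treesets[0]
        for arrangement in enumerate_valid_arrangements(ts, pterodroma.store):
            sums = []
            for v in ts.variants:
                if all(c in v for c in arrangement):
                    w = compute_weights(v)
                    sums.append(sum(w[c] for c in arrangement))
            assert Fraction(1) in sums


class TestDiff:
    def test_identical_checklists_produce_no_changes(self, vireo):
        checklist = vireo.checklists["split"]
        mapping = _solve(checklist, vireo.store)
        cs = diff_checklists(checklist, mapping, checklist, vireo.store)
        assert cs.changes == []
        assert len(cs.unchanged) == len(checklist.records)

    def test_genus_transfer_is_a_rename_not_a_new_concept(self):
        rng = random.Random(31)
        store = ConceptStore()
        cid = "8E833C63E70A547C"
        store.add_concept(cid, Kind.SPECIES)
        store.add_name(cid, "Francolinus levaillantoides", Rank.SPECIES)
        store.add_synonym("Scleroptila levaillantoides", cid)
        store.add_treeset(TreeSet(cid, [TreeVariant({}, extra_nodes=(cid,))]))
        old = Checklist("X", "1", 1990, [
            TaxonRecord("a", "Francolinus levaillantoides", Rank.SPECIES)])
        old_map = _solve(old, store)
        new = Checklist("X", "2", 2000, [
            TaxonRecord("a", "Scleroptila levaillantoides", Rank.SPECIES)])
        cs = diff_checklists(old, old_map, new, store)
        assert len(cs.renamed) == 1 and not cs.added and not cs.removed
        assert cs.renamed[0].concept == cid
        narrowed = candidates_from_diff(cs, new, store)
        result = solve_assignment(new, narrowed, store)
        assert result.by_id["a"].concept == cid

    def test_epithet_heuristic_works_without_a_store(self, vireo):
        old = vireo.checklists["split"]
        old_map = _solve(old, vireo.store)
        records = [TaxonRecord("s2", "Vireolanius cassinii", Rank.SPECIES)
                   if r.taxon_id == "s2" else r for r in old.records]
        new = Checklist("AOU", "42nd supplement", 2000, records)
        cs = diff_checklists(old, old_map, new)
        assert [c.taxon_id for c in cs.renamed] == ["s2"]
        assert cs.renamed[0].concept == vireo.key_ids["cassinii"]
        assert not cs.added and not cs.removed

    def test_addition_and_removal_detection(self, vireo):
        old = vireo.checklists["species_only"]
        old_map = _solve(old, vireo.store)
        new = Checklist("NewAuthority", "2.0", 2005, [
            TaxonRecord("s1", "Vireo solitarius", Rank.SPECIES),
            TaxonRecord("s9", "Tyrannus nova", Rank.SPECIES),
        ])
        cs = diff_checklists(old, old_map, new, vireo.store)
        assert [c.taxon_id for c in cs.added] == ["s9"]
        assert not cs.removed
        shrunk = Checklist("NewAuthority", "3.0", 2008, [])
        cs2 = diff_checklists(old, old_map, shrunk, vireo.store)
        assert [c.old_taxon_id for c in cs2.removed] == ["s1"]


class TestMonotonicity:
    def test_adding_subspecies_never_widens_the_solution_set(self, poicephalus):
        store = poicephalus.store
        ambiguous = poicephalus.checklists["two_species"]
        informed = poicephalus.checklists["with_subspecies"]
        n_amb = len(brute_force_solutions(
            ambiguous, resolve_candidates(ambiguous, store), store))
        n_inf = len(brute_force_solutions(
            informed, resolve_candidates(informed, store), store))
        assert n_amb == 2
        assert n_inf == 1
        assert n_inf <= n_amb


class TestOracleEquivalence:
    @pytest.mark.parametrize("fixture_name,checklist_name", [
        ("vireo", "lumped"), ("vireo", "split"), ("vireo", "species_only"),
        ("pterodroma", "three_species"), ("pterodroma", "heraldica_lumped"),
        ("poicephalus", "two_species"), ("poicephalus", "with_subspecies"),
    ])
    def test_solver_matches_bruteforce_on_fixture_checklists(
            self, fixture_name, checklist_name):
        fx = tc.build_fixture(fixture_name)
        checklist = fx.checklists[checklist_name]
        cands = resolve_candidates(checklist, fx.store)
        solutions = brute_force_solutions(checklist, cands, fx.store)
        expected = expected_statuses(checklist, cands, fx.store, solutions)
        result = solve_assignment(checklist, cands, fx.store)
        for e in result:
            status, concept = expected[e.taxon_id]
            assert e.status is status
            if status is MappingStatus.MAPPED:
                assert e.concept == concept
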