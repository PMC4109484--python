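import random
from fractions import Fraction

import pytest

import taxonconcept as tc
from taxonconcept import (ConceptStore, Kind, Rank, TreeSet, TreeVariant,
                          compute_weights, enumerate_valid_arrangements,
                          group_children, merge_roots, reassign,
                          split_terminal, validate_treeset)
from taxonconcept.edits import elevate

from helpers import collapsed_leaf_set


def _two_species_store(n_a=2, n_b=2, seed=11):
    """Two independent single-species trees with n_a / n_b subspecies."""
    rng = random.Random(seed)
    store = ConceptStore()
    tops = []
    for n in (n_a, n_b):
        sp = store.new_id(rng)
        store.add_concept(sp, Kind.SPECIES)
        if n == 1:
            store.add_treeset(TreeSet(sp, [TreeVariant({}, extra_nodes=(sp,))]))
        else:
            kids = []
            for _ in range(n):
                c = store.new_id(rng)
                store.add_concept(c, Kind.SUBSPECIES)
                kids.append(c)
            store.add_treeset(TreeSet(sp, [TreeVariant({sp: kids})]))
        tops.append(sp)
    return store, tops, rng


class TestSplitTerminal:
    def test_split_extends_every_variant_without_new_variant(self, vireo):
        store, k = vireo.store, vireo.key_ids
        before = {c: store.leaf_set(c) for c in store.treesets[0].nodes}
        new = split_terminal(k["pinicolus"], 2, store, random.Random(0))
        ts = store.treesets[0]
        assert len(new) == 2
        assert len(ts.variants) == 1
        assert ts.leaf_set(k["pinicolus"]) == frozenset(new)
        # pre-existing circumscriptions unchanged once the refinement is
        # collapsed back
        refinement = {c: k["pinicolus"] for c in new}
        for cid, leaves in before.items():
            assert collapsed_leaf_set(store, cid, refinement) == leaves

    def test_new_children_halve_the_former_leaf_weight(self, vireo):
        store, k = vireo.store, vireo.key_ids
        new = split_terminal(k["notius"], 2, store, random.Random(1))
        w = compute_weights(store.treesets[0].variants[0])
        assert w[k["notius"]] == Fraction(1, 15)
        assert all(w[c] == Fraction(1, 30) for c in new)

    def test_repeated_split_nests(self, vireo):
        store, k = vireo.store, vireo.key_ids
        first = split_terminal(k["montanus"], 2, store, random.Random(2))
        second = split_terminal(first[0], 2, store, random.Random(3))
        ts = store.treesets[0]
        assert len(ts.variants) == 1
        assert ts.leaf_set(k["montanus"]) == frozenset(second) | {first[1]}

    def test_internal_node_cannot_be_split(self, vireo):
        with pytest.raises(tc.EditError):
            split_terminal(vireo.key_ids["plumbeus"], 2, vireo.store)

    def test_result_validates(self, vireo):
        split_terminal(vireo.key_ids["alticola"], 3, vireo.store,
                       random.Random(4))
        assert validate_treeset(vireo.store.treesets[0]).ok


class TestMergeRoots:
    def test_merge_makes_equal_halves(self):
        store, (a, b), rng = _two_species_store(1, 1)
        root = merge_roots(a, b, store, rng, kind=Kind.SPECIES)
        ts = store.treesets[0]
        assert len(store.treesets) == 1
        w = compute_weights(ts.variants[0])
        assert w[root] == 1 and w[a] == w[b] == Fraction(1, 2)
        assert validate_treeset(ts).ok

    def test_arrangements_include_lump_and_split(self):
        store, (a, b), rng = _two_species_store(1, 1)
        root = merge_roots(a, b, store, rng, kind=Kind.SPECIES)
        arrangements = enumerate_valid_arrangements(store.treesets[0], store)
        assert frozenset({root}) in arrangements
        assert frozenset({a, b}) in arrangements

    def test_merging_a_tree_with_itself_fails(self):
        store, (a, b), rng = _two_species_store(2, 2)
        with pytest.raises(tc.EditError):
            merge_roots(a, a, store, rng)

    def test_non_root_arguments_fail(self, vireo):
        store, k = vireo.store, vireo.key_ids
        other = ConceptStore()  # build a second tree inside the same store
        sp = store.new_id(random.Random(7))
        store.add_concept(sp, Kind.SPECIES)
        store.add_treeset(TreeSet(sp, [TreeVariant({}, extra_nodes=(sp,))]))
        with pytest.raises(tc.EditError):
            merge_roots(k["cassinii"], sp, store)

    def test_leaf_sets_unchanged(self):
        store, (a, b), rng = _two_species_store(3, 2)
        before = {c: store.leaf_set(c)
                  for ts in store.treesets for c in ts.nodes}
        merge_roots(a, b, store, rng)
        for cid, leaves in before.items():
            assert store.leaf_set(cid) == leaves


class TestGroupChildren:
    def test_group_adds_alternate_variant(self, vireo):
        store, k = vireo.store, vireo.key_ids
        before_edges = store.treesets[0].variants[0].edges
        new = group_children(k["vireo_sl"], {k["cassinii"], k["plumbeus"]},
                             store, rng=random.Random(5), kind=Kind.SPECIES)
        ts = store.treesets[0]
        assert len(ts.variants) == 2
        assert ts.variants[0].edges == before_edges  # original untouched
        assert ts.leaf_set(new) == \
            ts.leaf_set(k["cassinii"]) | ts.leaf_set(k["plumbeus"])
        assert validate_treeset(ts).ok

    def test_arrangement_count_grows(self, vireo):
        store, k = vireo.store, vireo.key_ids
        ts = store.treesets[0]
        assert len(enumerate_valid_arrangements(ts, store)) == 2
        group_children(k["vireo_sl"], {k["cassinii"], k["plumbeus"]},
                       store, rng=random.Random(6), kind=Kind.SPECIES)
        arrangements = enumerate_valid_arrangements(store.treesets[0], store)
        assert len(arrangements) == 3

    def test_degenerate_subsets_fail(self, vireo):
        store, k = vireo.store, vireo.key_ids
        with pytest.raises(tc.EditError):
            group_children(k["vireo_sl"], {k["cassinii"]}, store)
        with pytest.raises(tc.EditError):
            group_children(k["vireo_sl"],
                           {k["vireo_ss"], k["cassinii"], k["plumbeus"]},
                           store)


class TestReassign:
    def test_reproduces_the_alternate_petrel_arrangement(self):
        # start from root -> {a, bc}, bc -> {b, c}; moving c to a yields the
        # contradictory arrangement root -> {ac', b}
        rng = random.Random(8)
        store = ConceptStore()
        ids = {}
        for key in ("root", "bc", "a", "b", "c"):
            ids[key] = store.new_id(rng)
            store.add_concept(ids[key], Kind.SPECIES)
        store.add_treeset(TreeSet(ids["root"], [TreeVariant({
            ids["root"]: {ids["a"], ids["bc"]},
            ids["bc"]: {ids["b"], ids["c"]},
        })]))
        res = reassign({ids["c"]}, ids["bc"], ids["a"], store, rng)
        ts = store.treesets[0]
        assert res["new_root"] is None
        assert res["b_prime"] == ids["b"]  # collapsed to the old terminal
        assert len(ts.variants) == 2
        new = ts.variants[1]
        assert new.children(ids["root"]) == {res["a_prime"], ids["b"]}
        assert new.leaf_set(res["a_prime"]) == {ids["a"], ids["c"]}
        assert validate_treeset(ts).ok

    def test_between_independent_trees_creates_shared_root(self):
        store, (a, b), rng = _two_species_store(3, 2)
        moved = sorted(store.leaf_set(a))[0]
        before = {c: store.leaf_set(c)
                  for ts in store.treesets for c in ts.nodes}
        res = reassign({moved}, a, b, store, rng)
        assert res["new_root"] is not None
        ts = store.treesets[0]
        assert len(store.treesets) == 1 and ts.root == res["new_root"]
        assert ts.leaf_set(res["a_prime"]) == before[b] | {moved}
        assert ts.leaf_set(res["b_prime"]) == before[a] - {moved}
        assert validate_treeset(ts).ok
        for cid, leaves in before.items():
            assert store.leaf_set(cid) == leaves

    def test_changed_intermediate_ancestors_are_dropped(self):
        # donor sits two levels below the shared root: the intermediate node
        # would change composition and must be absent from the new variant
        rng = random.Random(13)
        store = ConceptStore()
        ids = {}
        for key, kind in [("root", Kind.GROUP), ("mid", Kind.GROUP),
                          ("a", Kind.SPECIES), ("x", Kind.SPECIES),
                          ("t", Kind.SPECIES)]:
            ids[key] = store.new_id(rng)
            store.add_concept(ids[key], kind)
        leaves_a, leaves_x = [], []
        for i in range(2):
            for key_list, prefix in ((leaves_a, "a"), (leaves_x, "x")):
                c = store.new_id(rng)
                store.add_concept(c, Kind.SUBSPECIES)
                key_list.append(c)
        store.add_treeset(TreeSet(ids["root"], [TreeVariant({
            ids["root"]: {ids["mid"], ids["t"]},
            ids["mid"]: {ids["a"], ids["x"]},
            ids["a"]: leaves_a,
            ids["x"]: leaves_x,
        })]))
        res = reassign({leaves_a[0]}, ids["a"], ids["t"], store, rng)
        ts = store.treesets[0]
        new = ts.variants[1]
        assert ids["mid"] not in new       # its composition would have changed
        assert ids["x"] in new             # unaffected sibling re-hung intact
        assert new.leaf_set(ids["x"]) == frozenset(leaves_x)
        assert validate_treeset(ts).ok

    def test_degenerate_moves_fail(self):
        store, (a, b), rng = _two_species_store(2, 2)
        with pytest.raises(tc.EditError):
            reassign(set(), a, b, store, rng)
        with pytest.raises(tc.EditError):
            reassign(store.leaf_set(a), a, b, store, rng)  # a lump


def test_elevation_is_a_label_not_a_tree_change(vireo):
    store, k = vireo.store, vireo.key_ids
    edges_before = store.treesets[0].variants[0].edges
    elevate(k["ss_nominate"], "Vireo solitarius", store, Rank.SPECIES)
    assert store.treesets[0].variants[0].edges == edges_before
    assert k["ss_nominate"] in store.lookup_name("Vireo solitarius")
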