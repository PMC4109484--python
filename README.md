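# taxonconcept

Scientific names are poor identifiers of biological entities: a valid name
refers unambiguously only to its type specimen, while the *circumscription* —
the set of populations a usage of the name actually denotes — shifts with
every split, lump, and reassignment. `taxonconcept` is a small toolkit for
managing **taxonomic concepts** instead of names: every distinct
circumscription cluster receives one opaque 16-hex-character identifier
(e.g. `2624054ED644AABB`), identifiers are organised into rooted **concept
trees** (with alternate variants where authorities genuinely contradict each
other), and published checklists are mapped onto those identifiers
automatically.

It is written for biodiversity-informatics work: curators maintaining a
concept register across checklist editions, and data managers who need to
resolve which circumscription an old record's name referred to.

## The core idea: fractional weights

Every node of a concept tree gets an exact rational weight: the root has
weight 1 and each child receives an equal fraction of its parent's weight,

    w(root) = 1,        w(child) = w(parent) / |children(parent)|.

A complete, internally consistent listing of concepts from one tree then sums
to **exactly** 1 (all arithmetic uses `fractions.Fraction`; sums are equality
tests, never tolerances). Mapping a checklist means searching, per tree, for
the unique combination of one candidate concept per name whose species-level
weights sum to the scope-adjusted total without placing two same-rank usages
on one branch or breaking parent–descendant links. One surviving combination
⇒ the records are `mapped`; several ⇒ `ambiguous` (reported, never guessed);
none ⇒ `conflict`; names unknown to the store ⇒ `unmapped_new`.

Seven advisory consistency rules (weight sums at species and subspecies
level, uniqueness of the attaining combination, one record per concept,
no same-rank concepts along one branch, checklist parent links mirroring
tree ancestry, and shared root/terminals across alternate variants) are
checked by the validator and reported with rule numbers.

## Worked example

The package ships the Solitary Vireo complex as a generated fixture: one tree
rooted at *Vireo solitarius* s.l., split into *V. solitarius* s.s.,
*V. cassinii* and *V. plumbeus*, each with subspecies, and the nominal
*plumbeus* subspecies further resolved into *jacksoni* and the remainder.

```sh
$ taxonconcept fixture --name vireo -o demo
$ taxonconcept weights --tree demo/store.yaml --root 6BE1679F6AE28652
conceptID,weight,display
0221BE3E456E4249,1/6,0.167
0841D5824CBF5F95,1/3,0.333
0DE84F11832EA24F,1/15,0.067
139139975CC4A179,1/30,0.033
...
```

The three species-level children each carry exactly 1/3 (displayed 0.333),
their two-way subspecies 1/6 (0.167), the five *plumbeus* subspecies 1/15
(0.067), and the *jacksoni*/remainder pair 1/30 (0.033) — so any valid
arrangement (the lump alone, or the three splits, with or without their
subspecies) totals exactly 1.

Mapping the post-split checklist edition resolves every name, including the
homonymous *Vireo solitarius* (two concepts bear it) and the homonymous
nominal trinomial *V. p. plumbeus* (with or without *jacksoni*), purely from
the weight sums:

```sh
$ taxonconcept map --tree demo/store.yaml --checklist demo/checklist_split.csv -o demo/map.csv
$ head -3 demo/map.csv
taxonID,scientificName,status,conceptID,candidates,variant
s1,Vireo solitarius,mapped,EB6FA7CD62DE963A,6BE1679F6AE28652;EB6FA7CD62DE963A,0
s1.1,Vireo solitarius solitarius,mapped,0221BE3E456E4249,0221BE3E456E4249,0
```

`s1` had two candidates and was pinned to the *sensu stricto* concept
(weight 0.333) because the checklist also lists *cassinii* and *plumbeus*.
Validation of the result is clean:

```sh
$ taxonconcept validate --tree demo/store.yaml \
    --checklist demo/checklist_split.csv --mapping demo/map.csv
rule,subjects,message
```

Other subcommands: `relate` (congruent / includes / overlaps / excludes /
unrelated, from leaf-set algebra), `edit` (declarative split / merge / group /
reassign / elevate events), `diff` (classify a new checklist edition against
a mapped one), and `simulate` (seeded random checklist histories with
ground-truth mappings). The equivalent library API lives in
`taxonconcept.*` — see `docs/methods.md` for the model and its assumptions.

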