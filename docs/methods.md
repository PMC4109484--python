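# Methods

## The data model

A *taxonomic concept* is a name usage anchored to a publication whose
circumscription can be inferred from that source. Concepts that denote the
same set of populations are congruent and share one identifier — an opaque,
random, 16-character uppercase hexadecimal key. Because congruent concepts
collapse onto one ID, all relationships are recorded between IDs, which keeps
the relationship table linear in the number of *distinct* circumscriptions
rather than quadratic in the number of published usages.

IDs are arranged in rooted **concept trees** whose parent→child edges mean
strict circumscription inclusion. Trees are kept small on purpose: one tree
spans a superspecies complex or a set of species that some authority has ever
lumped or recombined; genera and families are deliberately not registered
(congruence at those levels is answerable by comparing the species-level
trees they contain). Where authorities contradict each other, a tree carries
several **variants**. All variants share the root and the terminal set, and
any intermediate node present in more than one variant subtends the same
terminals in each — otherwise one ID would denote two different
circumscriptions, which the model forbids. Every node therefore has a
well-defined, variant-independent *leaf set*, and the pairwise predicates
(congruent, includes, included-in, overlaps, excludes) are pure leaf-set
algebra. Concepts never co-modelled under a shared root are reported
`unrelated`, not `excludes`: the store cannot certify disjointness it has
never represented.

Names attach to concepts in two ways: rank-tagged labels (how a publication
used the name) and a synonym table (orthographic variants, genus transfers,
gender emendations, vernaculars). Lookup is exact-string after
canonicalization (whitespace collapsed, genus capitalized, epithets
lower-cased); fuzzy matching is out of scope. Two special conventions:

* **Monotypic species** and their nominal subspecies are one ID with two
  rank-tagged labels, never two nodes (their circumscriptions are identical).
* **Hybrids** are IDs linked to two or more parental IDs but excluded from
  trees, weights and validation sums.

## Fractional weights

The root of a variant has weight 1; each child receives its parent's weight
divided by the number of children. All arithmetic is exact rational
(`fractions.Fraction`): 1/3 is stored as 1/3 and rendered as `0.333` only for
display (three decimals). This matters because the validation predicate is
*equality*: a complete arrangement sums to exactly 1, and a floating-point
implementation would manufacture false violations at deep trees (weights such
as 1/30 compound quickly). Conservation — children summing exactly to their
parent — is asserted by property tests over random trees.

Regional checklists use the same machinery on a pruned tree: the scope is a
set of terminal IDs, leaves outside it are removed, empty nodes disappear,
and a node left with one child passes its full weight down. Translating a
geographic region into a leaf set is curation, not computation, so scope is
always supplied explicitly.

## Mapping a checklist

Checklists are full snapshots (a partial revision is treated as the whole
list re-published with the changes applied). Mapping runs in two stages:

1. **Candidate resolution.** Every record's canonical name is looked up
   against labels and synonyms. An empty candidate set marks a potential new
   concept (`unmapped_new`).
2. **Assignment search.** Records are partitioned into independent groups,
   one per concept tree (trees connected by a shared homonym or by a
   checklist parent link are merged into one group). Within a group the
   search enumerates one candidate per record and, per tree, each variant,
   keeping combinations in which — in at least one variant — all chosen IDs
   are present, no two same-rank records sit on one ancestor–descendant
   branch, species-level weights sum exactly to the scope total, each
   species' listed subspecies sum exactly to that species' weight, no ID is
   used twice (monotypic nominal alias excepted), and every checklist parent
   link is mirrored by tree ancestry. Solutions are deduplicated by ID
   assignment, since contradictory variants often agree on the mapping.

Exactly one surviving assignment ⇒ `mapped`. Several ⇒ records whose ID
differs across solutions are `ambiguous` with all alternatives listed;
ambiguity is never resolved by heuristics — curator decisions enter as an
explicit override file. None ⇒ `conflict`, which indicates either a concept
new to the store or a mis-constructed tree; distinguishing the two is left to
the curator. Per-tree decomposition is what keeps the search tractable; a
configurable cap (default 10⁶ combinations per group) guards pathological
homonymy, and exceeding it raises an error rather than silently truncating.

Uniqueness is not an accident of the examples: listing more structure (e.g.
subspecies rows) only removes solutions, never adds them, so an ambiguous
checklist can be disambiguated by a later, more detailed edition — the
monotonicity the tests assert.

Versioned authorities are diffed rather than re-resolved: records matching by
canonical name and rank are `unchanged`, records matching through the synonym
table or by identical epithets are `renamed` (genus transfer or gender
emendation — same ID, new string), and the remainder are additions/removals.
The diff narrows candidate sets before the assignment search.

## Validation rules

Seven advisory rules are checked; all findings are report entries ordered by
rule number then subject, never exceptions (the CLI's `--strict` turns a
non-empty report into a non-zero exit):

1. species-level weights within a tree sum to the scope total in ≥ 1 variant
   and never exceed it in any;
2. only one candidate combination attains that total (checked by re-running
   the assignment search; flagged only when a record *claimed* unique takes
   different IDs across surviving solutions);
3. a species' listed subspecies sum to the species' own weight;
4. one record per ID, except the monotypic nominal alias;
5. no two same-rank records along one branch;
6. checklist parent links mirror tree ancestry;
7. alternate variants share root and terminals, shared intermediates keep
   identical terminal sets (plus structural soundness: single root, no
   cycles, no one-child nodes).

Rules 1–3 are defined for species/subspecies sums, so `other`-rank records
(field pairs, assemblages) are exempt from them but still subject to 4–6.
Sum checks above the species level are omitted: higher taxa are fully
specified by the species they contain.

## Edits

Published concepts are permanent, so edits are append-only and never change
an existing ID's leaf set:

* `split_terminal` refines a terminal into n new children in every variant
  (no new variant — the refinement contradicts nothing);
* `merge_roots` joins two independent trees under a new root (variants
  combine pairwise);
* `group_children` lumps a proper subset of a node's children under a new
  intermediate ID, as a new variant;
* `reassign` moves terminals between species, creating A′ (recipient + moved)
  and B′ (donor − moved) in a new variant under a shared root (created by a
  merge if the species were in independent trees). Ancestors strictly between
  the two species and their nearest common ancestor would change composition,
  so they are omitted from the new variant and their unaffected children
  re-hang under the common ancestor; if B′ collapses to a single existing
  terminal, that terminal's ID is reused (they are congruent).
* `elevate` records a new rank-tagged name for an existing ID (raising a
  subspecies to species changes labels, not circumscriptions).

Minimizing variants is a design goal: only the two genuinely contradictory
edits create them.

## Serialization

The store is one YAML document (concepts with kinds and rank-tagged names;
trees as root + variants of parent→children lists; synonym rows; hybrid
links), schema-validated on load with messages naming each offending path.
Checklists and mappings are UTF-8 CSV with Darwin Core Taxon headers
(`taxonID, scientificName, taxonRank, parentNameUsageID, vernacularName`) and
leading `# key: value` metadata lines (authority, version, year, scope).
Writers sort everything they reasonably can, so identical inputs produce
byte-identical files. Darwin Core *Archives* (zip + meta descriptor) are not
supported — single-table text only.

## The simulator

`simulate_history` grows a random store through seeded revision histories so
that the mapper and validator can be tested against known truth without any
external data. Defaults: 8 base species, 1–4 subspecies each (1 ⇒ monotypic),
5 versions, per-species per-version event probabilities 0.15 split, 0.05
lump, 0.15 rename, 0.10 elevation, 0.05 reassignment, names drawn from a
synthetic Latin-like vocabulary. These sizes emulate a superspecies-scale
register revised over a handful of editions — the scale at which concept
curation actually happens — while keeping a 100-history test run under a few
seconds.

Name reuse mirrors nomenclatural practice: a split's first daughter keeps the
parent trinomial (the remainder concept becomes a homonym of the broader
one), an elevated nominate subspecies takes the old binomial, a lump keeps
the senior name, and a reassignment's A′/B′ keep the recipient's/donor's
binomials. These homonyms are structurally forced and always resolvable from
the weight sums when subspecies are listed. `homonym_rate` injects
*additional* reuse (retired binomials recycled onto unrelated concepts,
epithets repeated across trees); with subspecies omitted this produces
genuinely ambiguous checklists, and the tests assert that every such case is
*reported* as ambiguity, never silently mis-assigned.

Each version is emitted as a full-snapshot checklist plus its true mapping,
together with a deep copy of the store as it stood at publication — mapping
version *k* against the store of version *k+n* is a different (harder)
problem, because names coined later can shadow old usages.

What the simulator does **not** emulate: misspellings and OCR noise (no fuzzy
matching anywhere), incomplete subspecies coverage within one authority,
geographic scope restrictions (all simulated checklists are global), genuinely
erroneous trees, and real nomenclatural acts with priority rules. Passing
tests therefore demonstrate the algebra and the search are correct under the
stated model, not that real checklists are free of cases needing curation.

## Numerical and procedural choices

* All weight comparisons are exact; display rounding is `%.3f`.
* Ordering everywhere is deterministic (candidates, reports and arrangements
  sorted by ascending ID string), so outputs are reproducible byte-for-byte.
* ID generation is seedable for tests and fixtures; without a seed a
  cryptographic source is used. Collisions re-draw silently.
* Fixture identifiers are drawn from a fixed per-fixture seed; structure and
  names never vary, so every derived number in the documentation is stable.
* `other`-kind assemblage concepts are stored outside tree variants unless
  explicitly placed in one.
* Degenerate inputs (empty scope, grouping a single child, moving all of a
  species' leaves — a lump, not a reassignment) are rejected with specific
  errors rather than guessed at.

## Known limitations

* Exact-string name matching only; a misspelled checklist name surfaces as
  `unmapped_new` instead of a near-match suggestion.
* Rule 2's uniqueness re-check is skipped for groups whose candidate product
  exceeds the combination cap (rules 1 and 3–6 still apply).
* The validator reports; it never repairs. Choosing between "new concept" and
  "broken tree" for a `conflict` record remains expert judgement.
* Record-level resolution of occurrence data (using locality or date to pick
  a circumscription) is outside the package's scope.
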