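# Methods

## The model: molecules and reactions as integer matrices

A molecular system of `n` heavy atoms is an ordered atom list plus a
symmetric `n x n` integer matrix `B` whose entry `B[i,j]` is the bond order
between atoms `i` and `j`.  The diagonal is zero, hydrogens are implicit
(atom `i` carries `t_i - rowsum_i(B)` of them), and formal charges are never
represented.  Each neutral element has two bonding caps:

| element | t (max total bond order) | b (max single-bond order) |
|---------|--------------------------|---------------------------|
| C       | 4                        | 3                         |
| N       | 3                        | 3                         |
| O       | 2                        | 2                         |

Carbon is tetravalent but cannot form a quadruple bond, hence `b = 3`.  The
oxygen caps follow from the octet rule plus the zero-formal-charge
constraint: a neutral oxygen with a triple bond would require a charge, so
`(t, b) = (2, 2)`.  These caps are data, not code — arbitrary
`ElementSpec` values are accepted, and the enumeration, counting and
canonicalization machinery is generic over them.

A reaction is the elementwise difference of two systems on the same atom
array, `T = B_product − B_sm`: positive entries are bonds formed, negative
entries bonds broken.  The **bond edit distance** of a transformation is
`Σ|T_ij| / 2` (each edit appears twice in the symmetric matrix).  It counts
unit bond-order changes, deliberately agnostic of mechanism or feasibility:
a Diels–Alder cycloaddition scores 6 although it is a single concerted step,
while a direct C–N cross-coupling scores 1 although it needs a whole
catalytic cycle.

## The 8-atom amine–acid system

All headline computations run on the reaction center of amine–acid
coupling: the amine nitrogen with its alpha and beta carbons, and the
carboxyl group (C plus two oxygens) with its alpha and beta carbons —
5 C, 1 N, 2 O.  The fixed row convention is

```
0 amine beta-C   1 amine alpha-C   2 acid beta-C   3 acid alpha-C
4 carboxyl C     5 N               6 O (C=O)       7 O (C-OH)
```

Results are invariant to this choice; it only fixes matrix layout.  Four
starting-material templates cover the hybridization pairings of the two
partners (`sp3/sp3`, `sp3/sp2`, `sp2/sp3`, `sp2/sp2`).  The sp2 variant of a
partner places a double bond between its alpha and beta carbons (vinylamine
or acrylic-acid core).  This encoding is a design choice — the hybridization
of the reacting atoms is what matters, and the alpha–beta pi bond is the
minimal way to impose it on the 8-atom array — and the template matrices are
swappable via `starting_material_templates(overrides=...)` so alternative
encodings can be compared.  A product's distance is the minimum over the
four templates.

## Exhaustive enumeration

`iter_matrices` generates every symmetric, zero-diagonal matrix satisfying
the per-pair cap `min(b_i, b_j)` and per-row total `≤ t_i`, row by row: row
`i` is initialized by symmetry from the previously fixed columns and
extended with every admissible completion, in lexicographically ascending
order.  The stream is deterministic, emits each matrix exactly once, and
deliberately keeps the all-zero matrix and disconnected systems —
connectivity is a chemical filter applied later, not a matrix-level
constraint.  Checkpointing is by first-row prefix
(`resume_after_first_row`), with `count_by_first_row` giving the per-prefix
tallies needed to resume a long run.

Counting is separated from materialization: `count_matrices` runs a dynamic
program over remaining per-atom capacities and returns the exact stream
length in milliseconds.  For the 8-atom amine–acid array it gives
**55,964,558** valid matrices.

Correctness rests on an independent oracle: `brute_force_enumerate` tries
every upper-triangle assignment and keeps the valid ones.  The test suite
asserts exact set equality between the pruned stream and the oracle for
every atom multiset over {C, N, O} with up to five atoms, and the
acceptance suite re-runs the comparison against a second, vectorized oracle
implemented independently in the tests.

For full-scale runs, `fastpath` re-implements the same mathematics
compiled: each 28-entry upper triangle packs into two-bit fields of one
`uint64` (first pair most significant, so integer order = lexicographic
order), enumeration is a numba depth-first search, and the whole 56M-matrix
sweep takes under a minute on one CPU.  Set equality between the compiled
and reference paths is asserted on small and mid-size arrays.

## Degeneracy and deduplication

Chemically indistinguishable atoms — the two carboxylate oxygens, and in
the unsubstituted system all five carbons — make distinct matrices describe
the same chemistry.  The degeneracy group is the product of symmetric
groups on the declared classes (`S5 x S2`, order 240, for the default
array).  Two levels of deduplication are used:

* **Matrix level.**  `canonical_matrix` returns the lexicographically
  minimal matrix over the group; `count_orbits` computes the number of
  classes without enumerating anything, via Burnside's lemma.  The number
  of matrices fixed by a permutation is itself computed by a dynamic
  program over the permutation's orbits on atom pairs (entries constant per
  orbit, one capacity per atom cycle).  For the default array this gives
  **282,658** orbits under the full group, independently confirmed by the
  compiled canonical-labeling path (`numpy.unique` over canonized keys
  yields exactly the same number).  Under the oxygen swap alone the count
  is **29,328,894**.  Note the structural bound: an involution can at most
  halve a set, and only when nothing is fixed, so any oxygen-swap dedup of
  the 55,964,558 matrices must leave at least 27,982,279 classes
  (2,693,230 matrices are oxygen-symmetric, whence 29,328,894).

* **Structure level.**  `unique_products` decodes each matrix with RDKit,
  splits multi-molecule systems into connected components, keeps components
  with at least 4 heavy atoms, and deduplicates by canonical SMILES, which
  collapses any residual graph symmetry (every conceivable route to butane
  becomes one record).  The 4-heavy-atom rule is interpreted per connected
  component: the full 8-atom system always has 8 heavy atoms, so a
  whole-system reading would make the threshold vacuous; a
  `whole-system` mode is nevertheless provided.  On the default array this
  yields **222,740** unique products, with zero sanitization failures.

Each unique product records the minimum bond edit distance over *all*
matrices that produce it.  At full scale this is computed per orbit
representative: the distance of a permuted matrix to a template equals the
distance of the matrix to the inversely permuted template, so the orbit
minimum is a vectorized minimum over the deduplicated set of group-permuted
template triangles (at most 960, in practice fewer), then a group-by
minimum over products.

## Structural funnel

Products more than 6 bond edits from the nearest template, or with more
than 4 rings, are removed; ring count is the size of RDKit's smallest set
of smallest rings.  This leaves **80,941** products on the default run.
Both thresholds are parameters of `funnel_filter` and the pipeline config;
the filter is idempotent and monotone in both thresholds (property-tested).

A separate, configurable SMARTS list flags strained ring motifs for the
diversification workflow: bridgehead alkenes (an sp2 atom with three ring
bonds double-bonded to one with two, in rings of size ≤ 6), in-ring triple
bonds (ring size ≤ 7), in-ring cumulenes, edge-fused cyclopropanes
(bicyclobutane core) and spiro-linked cyclopropanes (spiropentane core).
These are deliberately coarse structural heuristics, not energy estimates:
ring-fusion-edge alkenes and 3-4 spiro systems pass, and anti-Bredt systems
where both alkene atoms are bridgeheads are missed.  The funnel counts
above do not depend on this list.

## Descriptors and shape space

The descriptor panel (HBD, HBA, MW, TPSA, fraction of sp3 carbons, QED,
Crippen logP, rotatable bonds, ring count) uses the standard RDKit
definitions throughout.  A second sp3-fraction variant with an
all-heavy-atom denominator (`FSP3_heavy`) is provided because on an 8-atom
reaction center that definition moves in steps of 1/8; the standard
carbon-denominator definition is the default and the one exported.

Shape coordinates come from a single ETKDGv3 distance-geometry embedding
per structure (hydrogens added, fixed seed, default 20): the three
principal moments of inertia are sorted ascending and normalized as
`NPR1 = PMI1/PMI3`, `NPR2 = PMI2/PMI3`, placing each molecule in the
rod–disc–sphere triangle (`NPR1 ≤ NPR2 ≤ 1`, `NPR1 + NPR2 ≥ 1`).  A single
conformer is intentional — the coordinates are a shape survey, not a
conformational analysis.  Embedding failure, which does occur for highly
strained cages, is recorded as `embed_status="failed"` and never raised.

## Late-stage diversification

To apply the enumerated library to substituted substrates, the eight
template atoms are located on the combined amine + acid molecule by
substructure search on its kekulized form (so aromatic alpha–beta bonds
appear as explicit double bonds; `sp3` patterns require `CX4` neighbours,
`sp2` patterns an alpha–beta double bond).  Multiple matches are all
reported and the first, in RDKit canonical order, is used.  Each
transformation then edits the mapped bond orders on an editable copy.
Because the library assumes unsubstituted carbons, edits can over-bond a
substituted carbon; such products fail sanitization and are rejected, as
are edits driving a bond order negative.  Optional predicates mirror the
published workflow: aromaticity retention (every aromatic substrate ring
must stay aromatic, checked by atom index), strained-motif rejection, ring
retention (every mapped atom in a k-ring of the substrate must remain in a
k-ring), and no-substituent-loss.  The last is operationalized as: all
unmapped heavy atoms must end up in a single fragment of the product
system — a transformation that splits the decorated parts apart has lost a
substituent.  (The zero transformation leaves the two substrates as two
fragments and is therefore rejected under this predicate; that is the
intended reading, since an uncoupled pair has not formed a product.)
Accepted plus categorized rejections always partition the library.

Reaction centers are generated by replaying the surviving transformations
on the simple 8-atom system, order-aligned with the diversified products
and not deduplicated: on the substituted substrate the alpha/beta carbons
are distinct, so centers that coincide on the simple system still represent
different products.

## Substructure search

Queries (enumerated products) are matched against a compound library with
RDKit substructure search; the frequency for a (query, compound) pair is
the number of symmetry-distinct embeddings (distinct atom index sets —
automorphic re-orderings of the same atoms count once).  With
`preserve_aromaticity=True` (default) both sides keep perceived
aromaticity, so an aliphatic query bond never matches along an aromatic
ring — a match that would correspond to a retrosynthetic disconnection
fragmenting the ring.  With `False`, both sides are kekulized and matching
is against the explicit single/double pattern, which is generally more
permissive (the frequency-dominance property is asserted on the fixture
library; it is not a theorem for arbitrary kekulizations).  Grouped
rankings split the top queries by elemental makeup ({C only, C+N, C+O,
C+N+O}); the chord-diagram export lists nonzero links with frequency bands
(1, 2–10, >10) and queries ordered by ascending edit distance, ties broken
by canonical SMILES.

The bundled 50-compound drug library is a synthetic stand-in for licensed
compound databases: familiar drug structures chosen to exercise amide
bonds, aromatic systems and polar functionality.  It supports offline
testing of the search machinery; absolute hit counts on it have no external
meaning.

## The fixture generator and what it does not emulate

`fixtures.toy_systems` provides tiny atom arrays whose matrix counts (3,
4, 3, 22, 219) are frozen from brute-force enumeration; the worked
examples encode the amide coupling (distance 2), a 6-carbon Diels–Alder
(distance 6) and a minimal C–N coupling (distance 1).  Passing tests on
these fixtures show the combinatorial and algebraic machinery is exact.
They do not show anything about synthetic feasibility, reaction kinetics,
stereochemistry (every product is treated as a single stereoisomer), or
charged species (nitro groups, ammonium salts and other formally charged
functionality are outside the representable space by construction).

## Numerical and engineering choices

* Matrices are `int8` throughout; packed `uint64` keys at full scale.
  Entries fit in [−4, 4] by the valence caps.
* All randomness (matrix sampling for spot checks, descriptor/PMI
  sampling, 3D embedding) flows from explicit seeds; reruns are
  byte-identical.
* The funnel runs in roughly 4–6 minutes on one CPU: enumeration < 1 min,
  canonicalization ~2.5 min, RDKit decoding of the 282,658 representatives
  ~1 min, ring/distance filtering ~1 min.  Peak memory is ~1 GB (two 56M
  `uint64` arrays).
* The pipeline writes descriptor/PMI tables for a seeded sample of the
  filtered products (default 2,000) — embedding all 80,941 survivors is
  supported (`props_sample=None`) but takes a few hours.
* Witness matrices for unique products are first-encountered in stream
  order; ties in grouped rankings break by canonical SMILES; every
  tie-break is deterministic.

## Known limitations

* The degeneracy-orbit intermediate differs from a published intermediate
  count for this system that attributes a reduction to oxygen equivalence;
  as shown above, no involution on the full matrix set can reach a value
  below half the set size, so this package reports the Burnside-exact
  29,328,894 (oxygen swap) and 282,658 (full group) instead.  The unique-
  product and filtered counts downstream (222,740 / 80,941) are unaffected.
* Canonical-SMILES deduplication inherits the toolkit's aromaticity and
  sanitization model; a different toolkit or version could shift the
  222,740 count slightly.  The manifest reports exact stage counts for
  comparison.
* Ionic and multi-center bonds, isotopic labeling and stereoisomer
  expansion are out of scope.
* The anti-Bredt/strain SMARTS list is heuristic and editable; it is not a
  substitute for an energetic strain model.
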