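# rxnmat

Exhaustive, valence-constrained enumeration of the amine–carboxylic acid
reaction space via integer bond matrices.

Amide coupling dominates medicinal chemistry, yet an amine and an acid
could in principle unite in millions of other ways.  `rxnmat` makes that
space concrete: it encodes molecular systems as symmetric heavy-atom
bond-order matrices **B** (hydrogens implicit, no formal charges) and
reactions as matrix differences **T = B_product − B_sm**, whose half-sum of
absolute entries is the *bond edit distance* — the number of unit
bond-order changes separating product from starting materials.

For the 8-atom reaction center of amine–acid coupling (amine N + α/β
carbons; CO₂H + α/β carbons: 5 C, 1 N, 2 O) the package:

1. **enumerates** every bond matrix obeying the octet rule, per-element
   caps C=(t4,b3), N=(3,3), O=(2,2) — 55,964,558 matrices;
2. **deduplicates** under atom degeneracy (interchangeable oxygens and
   unsubstituted carbons, the group S₅×S₂) by exact canonical labeling and
   Burnside counting — 282,658 orbits;
3. **decodes** each orbit to molecules, splits components, keeps products
   with ≥ 4 heavy atoms, dedupes by canonical SMILES — 222,740 unique
   products, each scored with its minimal edit distance over four
   hybridization templates (sp³/sp² amine × sp³/sp² acid);
4. **filters** to ≤ 4 rings and ≤ 6 bond edits — 80,941 products;
5. **profiles** physicochemical space (HBD/HBA, MW, TPSA, FSP3, QED, logP,
   ROTB, rings) and shape space (normalized PMI ratios from seeded ETKDG
   embeddings);
6. **diversifies** drug-like substrate pairs by replaying the
   transformation library at mapped reaction centers, with octet,
   aromaticity, strain and substituent-loss filters;
7. **searches** enumerated products as substructures of a compound
   library, with aromaticity preservation, composition grouping and
   chord-diagram data export.

The whole funnel runs in a few minutes on one CPU (compiled bit-packed
enumeration + canonicalization, then RDKit on one representative per
orbit).

## Worked example

```python
import rxnmat as rm

# the four amine-acid starting-material templates
sp3sp3 = rm.starting_material_templates()[0]
print(sp3sp3.system.to_smiles())        # CCC(=O)O.CCN

# the classic amide coupling: form N-C(=O), break C-OH
T = rm.amide_transformation()
print(rm.bond_edit_distance(T))         # 2
product = rm.apply_transformation(sp3sp3.system, T)
print(product.to_smiles())              # CCNC(=O)CC.O
print(rm.min_edit_distance(product))    # (2, 'sp3/sp3')
print(rm.compute_descriptors("CCC(=O)NCC").HBD)   # 1

# exact counts without materializing anything
from rxnmat.enumerate import EnumerationJob
arr = rm.amine_acid_array()
print(rm.count_matrices(EnumerationJob(arr)))     # 55964558
print(rm.count_orbits(arr))                       # 282658
```

The N-ethylpropanamide product sits 2 bond edits from the sp³/sp³
starting materials (one bond formed, one broken) and carries one
hydrogen-bond donor; the enumeration shows it is one of 55,964,558
conceivable outcomes, which collapse to 282,658 symmetry classes.

Full funnel and artifact directory:

```bash
rxnmat pipeline --out-dir out        # ~5-10 min, writes CSVs + manifest.json
rxnmat enumerate --atoms C2N1O1 --count-only   # 219
rxnmat dedupe --atoms default                  # 282658
```

`out/manifest.json` then reports every stage count
(`matrices=55964558, degeneracy_orbits=282658, unique_products=222740,
filtered_products=80941`) recomputed from the emitted CSVs.

## Layout

```
src/rxnmat/
  elements.py    bonding caps, atom arrays, the 8-atom amine-acid array
  system.py      bond matrices <-> RDKit molecules, validation
  enumerate.py   row-by-row stream, DP counter, brute-force oracle
  canon.py       degeneracy group, canonical labeling, Burnside, dedup
  fastpath.py    compiled bit-packed enumeration/canonicalization
  reactions.py   templates, transformation matrices, edit distance
  filters.py     ring/edit funnel, strain SMARTS, composition filters
  funnel.py      end-to-end funnel orchestration
  properties.py  descriptor panel, NPR shape coordinates, deltas
  diversify.py   late-stage diversification, reaction centers
  search.py      substructure frequencies, grouping, chord export
  pipeline.py    artifact directory + manifest
  fixtures.py    toy systems, synthetic drug library, worked examples
  cli.py         `rxnmat` command-line interface
```

See `docs/methods.md` for the model, design decisions and limitations.
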