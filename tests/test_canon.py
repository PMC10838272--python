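"""Degeneracy-group canonicalization, Burnside counting and product dedup."""

import numpy as np
import pytest

from rxnmat import (
    brute_force_enumerate,
    canonical_key,
    canonical_matrix,
    count_invariant_matrices,
    count_orbits,
    degeneracy_group,
    unique_products,
)
from rxnmat.elements import AtomArray, amine_acid_array
from rxnmat.enumerate import EnumerationJob, iter_matrices


def _orbit_count_brute(arr):
    """Partition the brute-force matrix set by the degeneracy group."""
    group = degeneracy_group(arr)
    mats = brute_force_enumerate(arr)
    n = len(arr)
    seen, orbits = set(), 0
    for raw in mats:
        B = np.frombuffer(raw, dtype=np.int8).reshape(n, n)
        key = canonical_key(B, arr, group)
        if key not in seen:
            seen.add(key)
            orbits += 1
    return orbits


class TestCanonicalKey:
    def test_symmetric_matrix_is_fixed_point(self):
        arr = AtomArray.from_symbols(["C", "O", "O"], [(1, 2)])
        B = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=np.int8)
        assert np.array_equal(canonical_matrix(B, arr), B)

    def test_asymmetric_pair_collapses(self):
        arr = AtomArray.from_symbols(["C", "O", "O"], [(1, 2)])
        B1 = np.array([[0, 2, 0], [2, 0, 0], [0, 0, 0]], dtype=np.int8)
        B2 = np.array([[0, 0, 2], [0, 0, 0], [2, 0, 0]], dtype=np.int8)
        assert canonical_key(B1, arr) == canonical_key(B2, arr)

    def test_permutation_crossing_elements_rejected(self):
        arr = AtomArray.from_symbols(["C", "O"])
        with pytest.raises(ValueError, match="crosses element types"):
            canonical_matrix(np.zeros((2, 2), dtype=np.int8), arr, group=[(1, 0)])

    def test_group_order(self):
        arr = amine_acid_array()
        assert len(degeneracy_group(arr)) == 120 * 2  # S5(C) x S2(O)


class TestBurnside:
    @pytest.mark.parametrize(
        "symbols,classes",
        [
            (["C", "O", "O"], [(1, 2)]),
            (["C", "C", "O", "O"], [(0, 1), (2, 3)]),
            (["C", "C", "C", "N"], [(0, 1, 2)]),
        ],
    )
    def test_orbit_count_matches_brute_partition(self, symbols, classes):
        arr = AtomArray.from_symbols(symbols, classes)
        assert count_orbits(arr) == _orbit_count_brute(arr)

    def test_identity_invariant_count_is_total(self):
        arr = amine_acid_array()
        from rxnmat import count_matrices

        ident = tuple(range(8))
        assert count_invariant_matrices(arr, ident) == count_matrices(
            EnumerationJob(arr)
        )

    def test_invariant_count_vs_direct_filter(self):
        arr = AtomArray.from_symbols(["C", "C", "O", "O"], [(0, 1), (2, 3)])
        perm = (1, 0, 2, 3)
        fixed = 0
        for raw in brute_force_enumerate(arr):
            B = np.frombuffer(raw, dtype=np.int8).reshape(4, 4)
            p = np.asarray(perm)
            if np.array_equal(B, B[np.ix_(p, p)]):
                fixed += 1
        assert count_invariant_matrices(arr, perm) == fixed


class TestUniqueProducts:
    def test_butane_routes_collapse(self, aa_array):
        # two different carbon chains both yield butane after losing the
        # NH2/CO2H heteroatom parts -> a single record
        def chain(idx):
            B = np.zeros((8, 8), dtype=np.int8)
            for a, b in zip(idx, idx[1:]):
                B[a, b] = B[b, a] = 1
            return B

        mats = [chain([0, 1, 2, 3]), chain([1, 2, 3, 4]), chain([4, 2, 0, 3])]
        recs = unique_products(mats, aa_array)
        butane = [r for r in recs.values() if r.smiles == "CCCC"]
        assert len(butane) == 1
        assert butane[0].n_heavy_atoms == 4

    def test_small_fragments_dropped(self, aa_array):
        B = np.zeros((8, 8), dtype=np.int8)  # all fragments are single atoms
        assert unique_products([B], aa_array) == {}

    def test_witness_regenerates_same_smiles(self, aa_array):
        from rxnmat import matrix_to_mol
        from rdkit import Chem

        mats = [B for B in __import__("rxnmat").enumerate.sample_matrices(aa_array, 40, seed=3)]
        recs = unique_products(mats, aa_array)
        for smi, rec in recs.items():
            mol = matrix_to_mol(rec.witness, aa_array)
            frag_smis = [Chem.MolToSmiles(f) for f in Chem.GetMolFrags(mol, asMols=True)]
            assert smi in frag_smis

    def test_dedup_idempotent(self, aa_array):
        from rxnmat.enumerate import sample_matrices

        mats = sample_matrices(aa_array, 60, seed=11)
        once = unique_products(mats, aa_array)
        twice = unique_products([r.witness for r in once.values()], aa_array)
        assert set(twice) == set(once)

    def test_whole_system_mode(self, aa_array):
        B = np.zeros((8, 8), dtype=np.int8)
        recs = unique_products([B], aa_array, mode="whole-system")
        assert list(recs) == ["C.C.C.C.C.N.O.O"]


def test_funnel_monotonicity_small():
    """|matrices| >= |orbits| >= |unique products| on a toy system."""
    arr = AtomArray.from_symbols(["C", "C", "O", "O"], [(0, 1), (2, 3)])
    mats = list(iter_matrices(EnumerationJob(arr)))
    orbits = count_orbits(arr)
    uniq = unique_products(mats, arr, min_heavy_atoms=1)
    assert len(mats) >= orbits >= len(uniq)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(0, 2), min_size=6, max_size=6), st.integers(0, 3))
def test_canonical_key_invariant_under_group_property(entries, which):
    """Permuting atoms within degeneracy classes never changes the key."""
    arr = AtomArray.from_symbols(["C", "C", "O", "O"], [(0, 1), (2, 3)])
    B = np.zeros((4, 4), dtype=np.int8)
    k = 0
    for i in range(4):
        for j in range(i + 1, 4):
            B[i, j] = B[j, i] = entries[k]
            k += 1
    from rxnmat import validate_matrix

    if not validate_matrix(B, arr)[0]:
        return
    group = degeneracy_group(arr)
    g = np.asarray(group[which % len(group)])
    assert canonical_key(B, arr) == canonical_key(B[np.ix_(g, g)], arr)
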