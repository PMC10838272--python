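"""Late-stage diversification and reaction-center generation."""

import numpy as np
import pytest
from rdkit import Chem

from rxnmat import (
    MolecularSystem,
    amide_transformation,
    apply_transformation,
    derive_transformation,
    diversify,
    generate_reaction_centers,
    map_template_atoms,
)
from rxnmat.enumerate import sample_matrices


class TestMapping:
    def test_simple_pair_maps_to_template_layout(self, templates):
        combined, mapping = map_template_atoms("CCN", "CCC(=O)O", "sp3/sp3")
        # rebuild the substrate matrix through the mapping: must equal the
        # sp3/sp3 template matrix
        kek = Chem.Mol(combined)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        B = np.zeros((8, 8), dtype=np.int8)
        for i in range(8):
            for j in range(i + 1, 8):
                bond = kek.GetBondBetweenAtoms(
                    mapping.row_to_atom[i], mapping.row_to_atom[j]
                )
                if bond is not None:
                    B[i, j] = B[j, i] = int(bond.GetBondTypeAsDouble())
        assert np.array_equal(B, templates[0].system.B)

    def test_aniline_mismatches_sp3_template(self):
        with pytest.raises(ValueError, match="pattern not found"):
            map_template_atoms("Nc1ccccc1", "CCC(=O)O", "sp3/sp3")

    def test_sp2_pair_matches_sp2_template(self):
        combined, mapping = map_template_atoms("Nc1ccccc1", "OC(=O)c1ccccc1", "sp2/sp2")
        assert len(mapping.row_to_atom) == 8
        assert len(set(mapping.row_to_atom.values())) == 8

    def test_multiple_matches_all_reported_first_used(self):
        # a diacid: two chemically distinct acid matches
        _, mapping = map_template_atoms("CCN", "OC(=O)CCCCC(=O)O", "sp3/sp3")
        assert len(mapping.all_matches) >= 2


class TestDiversify:
    def test_amide_transformation_on_substituted_pair(self):
        result = diversify(
            "NCCc1ccccc1", "OC(=O)CCc1ccccc1", [amide_transformation()]
        )
        assert result.surviving_indices == [0]
        prods = result.products[0].split(".")
        amide = Chem.CanonSmiles("O=C(CCc1ccccc1)NCCc1ccccc1")
        assert amide in [Chem.CanonSmiles(p) for p in prods]

    def test_zero_matrix_returns_substrates(self):
        result = diversify("CCN", "CCC(=O)O", [np.zeros((8, 8), dtype=np.int8)])
        assert result.products == [Chem.CanonSmiles("CCN.CCC(=O)O")]

    def test_octet_violating_edit_rejected(self):
        # +1 on the already saturated alpha-C/beta-C bond of a substituted
        # amine exceeds carbon valence once substituents are present
        T = np.zeros((8, 8), dtype=np.int8)
        T[0, 1] = T[1, 0] = 3
        result = diversify("CCN", "CCC(=O)O", [T])
        assert result.surviving_indices == []
        assert result.rejections["valence_violation"] == 1

    def test_negative_bond_order_categorized(self):
        T = np.zeros((8, 8), dtype=np.int8)
        T[0, 2] = T[2, 0] = -1
        result = diversify("CCN", "CCC(=O)O", [T])
        assert result.rejections["negative_bond_order"] == 1

    def test_rejection_categories_partition_library(self, aa_array):
        mats = sample_matrices(aa_array, 50, seed=17)
        tmplB = None
        from rxnmat import starting_material_templates

        tmplB = starting_material_templates()[0].system.B
        ts = [B.astype(np.int16) - tmplB for B in mats]
        result = diversify("NCCc1ccccc1", "OC(=O)CCc1ccccc1", ts, strained_filter=True)
        assert result.n_total == len(ts)

    def test_aromaticity_filter_on_sp2_pair(self, templates):
        # destroying the ring: add H2 across an aromatic bond of aniline via
        # the mapped alpha-beta bond (double -> single)
        T = np.zeros((8, 8), dtype=np.int8)
        T[0, 1] = T[1, 0] = -1
        res_keep = diversify(
            "Nc1ccccc1", "OC(=O)c1ccccc1", [T], template_id="sp2/sp2",
            keep_aromatic=True,
        )
        assert res_keep.rejections.get("aromaticity_broken", 0) == 1

    def test_consistency_with_enumeration_on_simple_pair(self, templates, aa_array):
        """On the unsubstituted pair, diversification just replays the
        enumerated products."""
        mats = sample_matrices(aa_array, 100, seed=23)
        tmpl = templates[0]
        ts = [B.astype(np.int16) - tmpl.system.B for B in mats]
        result = diversify("CCN", "CCC(=O)O", ts)
        assert result.surviving_indices == list(range(len(ts)))
        for B, smi in zip(mats, result.products):
            expected = MolecularSystem(aa_array, B).to_smiles()
            assert Chem.CanonSmiles(smi) == expected


class TestReactionCenters:
    def test_alignment_and_determinism(self, templates, aa_array):
        mats = sample_matrices(aa_array, 30, seed=29)
        ts = [B.astype(np.int16) - templates[0].system.B for B in mats]
        result = diversify("NCCc1ccccc1", "OC(=O)CCc1ccccc1", ts)
        centers = generate_reaction_centers(result.surviving_indices, ts, templates[0])
        assert len(centers) == len(result.products)
        assert centers == generate_reaction_centers(
            result.surviving_indices, ts, templates[0]
        )

    def test_amide_center(self, templates):
        ts = [amide_transformation()]
        centers = generate_reaction_centers([0], ts, templates[0])
        assert Chem.CanonSmiles("CCC(=O)NCC") in centers[0].split(".")

    def test_centers_not_deduplicated(self, templates):
        ts = [amide_transformation(), amide_transformation()]
        centers = generate_reaction_centers([0, 1], ts, templates[0])
        assert len(centers) == 2 and centers[0] == centers[1]
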