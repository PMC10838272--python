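"""Transformation matrices, bond edit distance and template scoring."""

import numpy as np
import pytest

from rxnmat import (
    MolecularSystem,
    Rejection,
    amide_transformation,
    apply_transformation,
    bond_edit_distance,
    derive_transformation,
    min_edit_distance,
)
from rxnmat.elements import AtomArray, amine_acid_array
from rxnmat.enumerate import sample_matrices
from rxnmat.fixtures import cn_coupling_example, diels_alder_example


class TestWorkedExamples:
    def test_amide_transformation_entries(self, templates):
        """The amide coupling changes exactly two bond pairs: the N-C(=O)
        bond forms (+1) and the C-OH bond breaks (-1)."""
        T = amide_transformation()
        nz = {(i, j): int(T[i, j]) for i in range(8) for j in range(i + 1, 8) if T[i, j]}
        assert nz == {(4, 5): 1, (4, 7): -1}
        assert bond_edit_distance(T) == 2
        product = apply_transformation(templates[0].system, T)
        assert derive_transformation(product, templates[0]).tolist() == T.tolist()

    def test_diels_alder_distance_six(self):
        sm, prod, T = diels_alder_example()
        assert bond_edit_distance(T) == 6
        assert np.array_equal(derive_transformation(prod, sm), T)
        assert apply_transformation(sm, T) == prod

    def test_cn_coupling_distance_one(self):
        _, _, T = cn_coupling_example()
        assert bond_edit_distance(T) == 1


class TestDeriveApply:
    def test_identity_transformation(self, templates):
        sm = templates[0].system
        T = derive_transformation(sm, templates[0])
        assert not T.any()
        assert bond_edit_distance(T) == 0

    def test_round_trip_on_random_products(self, templates, aa_array):
        for B in sample_matrices(aa_array, 100, seed=5):
            product = MolecularSystem(aa_array, B)
            for tmpl in templates:
                T = derive_transformation(product, tmpl)
                assert np.array_equal(tmpl.system.B + T, product.B)

    def test_dimension_mismatch_rejected(self, templates):
        small = MolecularSystem(
            AtomArray.from_symbols(["C", "O"]), np.zeros((2, 2), dtype=np.int8)
        )
        with pytest.raises(ValueError, match="mismatch"):
            derive_transformation(small, templates[0])

    def test_full_fragmentation(self, templates):
        sm = templates[0].system
        result = apply_transformation(sm, -sm.B)
        assert result.to_smiles() == "C.C.C.C.C.N.O.O"

    def test_negative_bond_order_rejection(self, templates):
        T = np.zeros((8, 8), dtype=np.int8)
        T[0, 2] = T[2, 0] = -1  # no such bond in the template
        result = apply_transformation(templates[0].system, T)
        assert isinstance(result, Rejection) and not result
        assert "negative" in result.detail

    def test_octet_violation_rejection(self, templates):
        T = np.zeros((8, 8), dtype=np.int8)
        T[4, 5] = T[5, 4] = 3  # over-bonds the carboxyl carbon
        result = apply_transformation(templates[0].system, T)
        assert isinstance(result, Rejection)


class TestMinDistance:
    def test_templates_score_zero_on_themselves(self, templates):
        for tmpl in templates:
            d, tid = min_edit_distance(tmpl.system, templates)
            assert d == 0 and tid == tmpl.id

    def test_amide_product_distance_two(self, templates):
        product = apply_transformation(templates[0].system, amide_transformation())
        d, tid = min_edit_distance(product, templates)
        assert d == 2 and tid == "sp3/sp3"

    def test_min_bounded_by_each_template(self, templates, aa_array):
        for B in sample_matrices(aa_array, 30, seed=9):
            product = MolecularSystem(aa_array, B)
            d, _ = min_edit_distance(product, templates)
            for tmpl in templates:
                assert d <= bond_edit_distance(derive_transformation(product, tmpl))


class TestMetricProperties:
    def test_edit_distance_is_a_metric(self, aa_array):
        mats = sample_matrices(aa_array, 30, seed=13)
        systems = [MolecularSystem(aa_array, B) for B in mats]

        def dist(a, b):
            return bond_edit_distance(derive_transformation(a, b))

        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c = (systems[i] for i in rng.integers(0, len(systems), 3))
            assert dist(a, b) == dist(b, a)
            assert (dist(a, b) == 0) == np.array_equal(a.B, b.B)
            assert dist(a, c) <= dist(a, b) + dist(b, c)

    def test_invariance_under_simultaneous_permutation(self, aa_array):
        rng = np.random.default_rng(2)
        mats = sample_matrices(aa_array, 10, seed=21)
        for B in mats:
            other = sample_matrices(aa_array, 1, seed=int(B.sum()) + 50)[0]
            perm = np.concatenate([rng.permutation(5), [5], 5 + 1 + rng.permutation(2)])
            d1 = bond_edit_distance(B - other)
            d2 = bond_edit_distance(
                B[np.ix_(perm, perm)] - other[np.ix_(perm, perm)]
            )
            assert d1 == d2

    def test_asymmetric_matrix_rejected(self):
        T = np.zeros((3, 3), dtype=np.int8)
        T[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            bond_edit_distance(T)


class TestReactionRecords:
    def test_line_round_trip(self, templates):
        from rxnmat import ReactionRecord, apply_transformation, score_product

        product = apply_transformation(templates[0].system, amide_transformation())
        rec = score_product(product, templates)
        assert rec.edit_distance == 2 and rec.template_id == "sp3/sp3"
        back = ReactionRecord.from_line(rec.to_line())
        assert back.template_id == rec.template_id
        assert back.edit_distance == rec.edit_distance
        assert back.product_key == rec.product_key
        assert np.array_equal(back.T, rec.T)
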