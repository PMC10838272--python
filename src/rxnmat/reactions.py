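"""Starting-material templates, transformation matrices and bond edit distance.

A reaction is the difference of two bond matrices on the same atom array:
``T = B_product - B_startingmaterial``.  Positive entries are bonds formed,
negative entries bonds broken.  The bond edit distance of a transformation is
half the sum of absolute entries (each edit appears twice in the symmetric
matrix).  Four starting-material systems are encoded for the 8-atom
amine-acid array, one per hybridization pairing of the amine and the acid;
the sp2 variant of a partner places a double bond between its alpha and beta
carbons (vinylamine / acrylic acid cores).  A product's distance is the
minimum over the four templates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .elements import amine_acid_array
from .system import MolecularSystem, SanitizationError, matrix_to_mol, validate_matrix

__all__ = [
    "StartingMaterialTemplate",
    "TEMPLATE_IDS",
    "starting_material_templates",
    "derive_transformation",
    "bond_edit_distance",
    "min_edit_distance",
    "apply_transformation",
    "Rejection",
]

TEMPLATE_IDS = ("sp3/sp3", "sp3/sp2", "sp2/sp3", "sp2/sp2")


@dataclass(frozen=True)
class StartingMaterialTemplate:
    """One amine + acid two-fragment system on the standard 8-atom array."""

    id: str
    system: MolecularSystem


def _template_matrix(amine_sp2: bool, acid_sp2: bool) -> np.ndarray:
    # atom order: 0 amine beta-C, 1 amine alpha-C, 2 acid beta-C,
    # 3 acid alpha-C, 4 carboxyl C, 5 N, 6 O(=C), 7 O(H)
    B = np.zeros((8, 8), dtype=np.int8)

    def setb(i: int, j: int, order: int) -> None:
        B[i, j] = B[j, i] = order

    setb(0, 1, 2 if amine_sp2 else 1)
    setb(1, 5, 1)
    setb(2, 3, 2 if acid_sp2 else 1)
    setb(3, 4, 1)
    setb(4, 6, 2)
    setb(4, 7, 1)
    return B


def starting_material_templates(
    overrides: Optional[dict[str, np.ndarray]] = None,
) -> tuple[StartingMaterialTemplate, ...]:
    """The four hybridization templates (amine/acid: sp3 or sp2 each).

    ``overrides`` maps template ids to replacement matrices, so alternative
    sp2 encodings can be swapped in without touching callers.
    """
    arr = amine_acid_array()
    out = []
    for tid, (am, ac) in zip(
        TEMPLATE_IDS, [(False, False), (False, True), (True, False), (True, True)]
    ):
        B = _template_matrix(am, ac)
        if overrides and tid in overrides:
            B = np.asarray(overrides[tid], dtype=np.int8)
        out.append(StartingMaterialTemplate(tid, MolecularSystem(arr, B)))
    return tuple(out)


def derive_transformation(
    product: MolecularSystem, sm: StartingMaterialTemplate | MolecularSystem
) -> np.ndarray:
    """Transformation matrix ``T = B_product - B_sm`` (int8, signed)."""
    sm_sys = sm.system if isinstance(sm, StartingMaterialTemplate) else sm
    if product.B.shape != sm_sys.B.shape:
        raise ValueError(
            f"dimension mismatch: product {product.B.shape} vs SM {sm_sys.B.shape}"
        )
    if product.atom_array.symbols != sm_sys.atom_array.symbols:
        raise ValueError("product and starting material use different atom arrays")
    return (product.B.astype(np.int16) - sm_sys.B.astype(np.int16)).astype(np.int8)


def bond_edit_distance(T: np.ndarray) -> int:
    """Half the sum of absolute transformation-matrix entries.

    Counts unit bond-order changes: an amide coupling (one bond formed, one
    broken) scores 2; a Diels-Alder scores 6; a single direct coupling 1.
    """
    T = np.asarray(T)
    if not np.array_equal(T, T.T):
        raise ValueError("transformation matrix must be symmetric")
    total = int(np.abs(T).sum())
    assert total % 2 == 0, "symmetric matrix has even absolute sum"
    return total // 2


def min_edit_distance(
    product: MolecularSystem,
    templates: Optional[tuple[StartingMaterialTemplate, ...]] = None,
) -> tuple[int, str]:
    """Minimum bond edit distance over the four templates, with the argmin id."""
    if templates is None:
        templates = starting_material_templates()
    best: tuple[int, str] | None = None
    for tmpl in templates:
        d = bond_edit_distance(derive_transformation(product, tmpl))
        if best is None or d < best[0]:
            best = (d, tmpl.id)
    assert best is not None
    return best


@dataclass(frozen=True)
class Rejection:
    """Why a transformation could not be applied to a system."""

    reason: str
    detail: str = ""

    def __bool__(self) -> bool:  # rejections are falsy results
        return False


def apply_transformation(
    system: MolecularSystem, T: np.ndarray
) -> MolecularSystem | Rejection:
    """Apply ``T`` to a system: ``B' = B + T`` if the result is a legal system.

    Returns the new system, or a :class:`Rejection` naming the violated rule
    (negative bond order, octet/cap violation, or sanitization failure).
    Invalid chemistry is an expected outcome during library application, so
    it is a value, not an exception.
    """
    T = np.asarray(T)
    if T.shape != system.B.shape:
        raise ValueError(f"dimension mismatch: {T.shape} vs {system.B.shape}")
    B2 = (system.B.astype(np.int16) + T.astype(np.int16)).astype(np.int8)
    ok, violations = validate_matrix(B2, system.atom_array)
    if not ok:
        return Rejection("invalid_matrix", "; ".join(violations))
    try:
        matrix_to_mol(B2, system.atom_array)
    except SanitizationError as exc:
        return Rejection("sanitization_failed", str(exc))
    return MolecularSystem(system.atom_array, B2)


@dataclass(frozen=True)
class ReactionRecord:
    """A scored reaction: product, template, transformation and distance."""

    product_key: str  # canonical SMILES of the product system
    template_id: str
    T: np.ndarray
    edit_distance: int

    def to_line(self) -> str:
        """One-record-per-line serialization:
        template id, space-separated lower-triangle of T, distance, SMILES."""
        n = self.T.shape[0]
        tri = " ".join(
            str(int(self.T[i, j])) for i in range(n) for j in range(i)
        )
        return f"{self.template_id}\t{tri}\t{self.edit_distance}\t{self.product_key}"

    @classmethod
    def from_line(cls, line: str, n: int = 8) -> "ReactionRecord":
        tid, tri, dist, smiles = line.rstrip("\n").split("\t")
        vals = [int(x) for x in tri.split()]
        T = np.zeros((n, n), dtype=np.int8)
        k = 0
        for i in range(n):
            for j in range(i):
                T[i, j] = T[j, i] = vals[k]
                k += 1
        return cls(smiles, tid, T, int(dist))


def score_product(
    product: MolecularSystem,
    templates: Optional[tuple[StartingMaterialTemplate, ...]] = None,
) -> ReactionRecord:
    """Best-template :class:`ReactionRecord` for one product system."""
    if templates is None:
        templates = starting_material_templates()
    d, tid = min_edit_distance(product, templates)
    tmpl = next(t for t in templates if t.id == tid)
    return ReactionRecord(
        product_key=product.to_smiles(),
        template_id=tid,
        T=derive_transformation(product, tmpl),
        edit_distance=d,
    )


def amide_transformation() -> np.ndarray:
    """The classic amide-coupling transformation on the 8-atom array.

    Forms the N-C(=O) bond and breaks the C-OH bond: entries (4,5) = +1 and
    (4,7) = -1 plus symmetric partners; distance 2.
    """
    T = np.zeros((8, 8), dtype=np.int8)
    T[4, 5] = T[5, 4] = 1
    T[4, 7] = T[7, 4] = -1
    return T
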