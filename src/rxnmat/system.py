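"""Molecular systems as symmetric bond-order matrices, and RDKit interconversion.

A *system* is an ordered heavy-atom list together with an n x n symmetric
integer matrix ``B`` whose (i, j) entry is the bond order between atoms i and
j.  Hydrogens are implicit: atom i carries ``t_i - rowsum(i)`` of them.  A
single matrix may encode several disconnected molecules, so conversion back
to structures yields dot-separated fragments.  Aromatic input is kekulized on
encoding so that every entry is a small integer; aromaticity is re-perceived
on decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .elements import AtomArray, DEFAULT_SPECS

RDLogger.DisableLog("rdApp.*")

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    4: Chem.BondType.QUADRUPLE,
}


class SanitizationError(ValueError):
    """A matrix satisfied the valence caps but RDKit could not sanitize it."""


@dataclass(frozen=True)
class MolecularSystem:
    """An atom array plus its symmetric bond-order matrix (int8)."""

    atom_array: AtomArray
    B: np.ndarray

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=np.int8)
        object.__setattr__(self, "B", B)
        ok, violations = validate_matrix(B, self.atom_array)
        if not ok:
            raise ValueError("invalid bond matrix: " + "; ".join(violations))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularSystem):
            return NotImplemented
        return (
            self.atom_array.symbols == other.atom_array.symbols
            and np.array_equal(self.B, other.B)
        )

    def __hash__(self) -> int:
        return hash((self.atom_array.symbols, self.B.tobytes()))

    @property
    def n(self) -> int:
        return len(self.atom_array)

    def implicit_h(self) -> np.ndarray:
        """Implicit hydrogen count per atom: t_i - rowsum(i)."""
        return np.asarray(self.atom_array.t) - self.B.sum(axis=1)

    def to_mol(self) -> Chem.Mol:
        return matrix_to_mol(self.B, self.atom_array)

    def to_smiles(self) -> str:
        """Canonical (dot-separated if multi-fragment) SMILES of the system."""
        return Chem.MolToSmiles(self.to_mol())

    def fragments(self) -> list[Chem.Mol]:
        """Connected components as individual sanitized molecules."""
        return list(Chem.GetMolFrags(self.to_mol(), asMols=True))


def validate_matrix(B, atom_array: AtomArray) -> tuple[bool, list[str]]:
    """Check all bond-matrix invariants; return (ok, violation messages).

    Invariants: square integer matrix matching the atom array; symmetric;
    zero diagonal; ``0 <= B[i,j] <= min(b_i, b_j)``; row sums at most
    ``t_i`` (so that implicit hydrogen counts are non-negative).
    """
    B = np.asarray(B)
    violations: list[str] = []
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        return False, [f"matrix is not square: shape {B.shape}"]
    if not np.issubdtype(B.dtype, np.integer):
        return False, [f"matrix entries are not integers (dtype {B.dtype})"]
    n = len(atom_array)
    if B.shape[0] != n:
        return False, [f"matrix size {B.shape[0]} != atom count {n}"]
    if not np.array_equal(B, B.T):
        violations.append("matrix is not symmetric")
    if np.any(np.diag(B) != 0):
        violations.append("nonzero diagonal (atom bonded to itself)")
    t = np.asarray(atom_array.t)
    b = np.asarray(atom_array.b)
    if np.any(B < 0):
        for i, j in zip(*np.nonzero(B < 0)):
            violations.append(f"negative bond order at ({i},{j})")
    cap = np.minimum.outer(b, b)
    over = (B > cap) & ~np.eye(n, dtype=bool)
    for i, j in zip(*np.nonzero(over)):
        if i < j:
            violations.append(
                f"bond order {B[i, j]} at ({i},{j}) exceeds cap {cap[i, j]}"
            )
    rowsum = B.sum(axis=1)
    for i in np.nonzero(rowsum > t)[0]:
        violations.append(f"octet violation row {i}: total order {rowsum[i]} > t={t[i]}")
    return not violations, violations


def mol_to_matrix(
    mol_input: str | Chem.Mol,
    atom_order: list[int] | None = None,
) -> MolecularSystem:
    """Encode a molecule (SMILES string or RDKit Mol) as a bond matrix.

    Aromatic systems are kekulized so every matrix entry is an integer bond
    order.  Only neutral molecules built from elements with registered
    bonding caps are accepted; hydrogens are dropped (kept implicit).

    Parameters
    ----------
    mol_input : str or Chem.Mol
        Molecule to encode.  Dot-separated SMILES encode multi-fragment
        systems in a single matrix.
    atom_order : list of int, optional
        Assignment of matrix rows to heavy atoms: ``atom_order[row]`` is the
        RDKit atom index placed at that row.  Defaults to RDKit order.
    """
    if isinstance(mol_input, str):
        mol = Chem.MolFromSmiles(mol_input)
        if mol is None:
            raise ValueError(f"could not parse SMILES {mol_input!r}")
    else:
        mol = Chem.Mol(mol_input)
        Chem.SanitizeMol(mol)
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() != 0:
            raise ValueError(
                f"charged atom {atom.GetSymbol()}{atom.GetFormalCharge():+d} at index "
                f"{atom.GetIdx()}: formal charges are not representable"
            )
        if atom.GetSymbol() not in DEFAULT_SPECS:
            raise ValueError(
                f"unsupported element {atom.GetSymbol()} at index {atom.GetIdx()}"
            )
    mol = Chem.RemoveHs(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    n = mol.GetNumAtoms()
    order = list(range(n)) if atom_order is None else list(atom_order)
    if sorted(order) != list(range(n)):
        raise ValueError("atom_order must be a permutation of all heavy-atom indices")
    pos = {a: row for row, a in enumerate(order)}
    B = np.zeros((n, n), dtype=np.int8)
    for bond in mol.GetBonds():
        i = pos[bond.GetBeginAtomIdx()]
        j = pos[bond.GetEndAtomIdx()]
        order_f = bond.GetBondTypeAsDouble()
        if order_f != int(order_f):
            raise ValueError(f"non-integer bond order {order_f} after kekulization")
        B[i, j] = B[j, i] = int(order_f)
    symbols = [mol.GetAtomWithIdx(order[row]).GetSymbol() for row in range(n)]
    return MolecularSystem(AtomArray.from_symbols(symbols), B)


def matrix_to_mol(B, atom_array: AtomArray) -> Chem.Mol:
    """Decode a bond matrix into a sanitized RDKit molecule.

    Places one atom per row, then one bond per nonzero lower-triangle entry.
    Implicit hydrogens fill the remaining valence automatically since no atom
    is charged.  Raises :class:`SanitizationError` when RDKit rejects the
    structure (callers in bulk pipelines catch and log it).
    """
    B = np.asarray(B)
    ok, violations = validate_matrix(B, atom_array)
    if not ok:
        raise ValueError("invalid bond matrix: " + "; ".join(violations))
    rw = Chem.RWMol()
    for sym in atom_array.symbols:
        rw.AddAtom(Chem.Atom(sym))
    n = len(atom_array)
    for i in range(n):
        for j in range(i):
            if B[i, j]:
                rw.AddBond(i, j, _BOND_TYPES[int(B[i, j])])
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rare on valence-legal input
        raise SanitizationError(f"sanitization failed: {exc}") from exc
    return mol


def system_from_smiles(smiles: str, atom_order: list[int] | None = None) -> MolecularSystem:
    """Convenience wrapper: SMILES -> :class:`MolecularSystem`."""
    return mol_to_matrix(smiles, atom_order)


def save_matrices_csv(systems, path) -> None:
    """Write systems on a shared atom array as flattened lower-triangle CSV.

    The header row holds the element symbols; each subsequent row is the
    strict lower triangle of one matrix in row-major order.
    """
    systems = list(systems)
    if not systems:
        raise ValueError("nothing to write")
    symbols = systems[0].atom_array.symbols
    n = len(symbols)
    idx = [(i, j) for i in range(n) for j in range(i)]
    with open(path, "w") as fh:
        fh.write(",".join(symbols) + "\n")
        for s in systems:
            if s.atom_array.symbols != symbols:
                raise ValueError("mixed atom arrays in one matrix file")
            fh.write(",".join(str(int(s.B[i, j])) for i, j in idx) + "\n")


def load_matrices_csv(path) -> list[MolecularSystem]:
    """Inverse of :func:`save_matrices_csv`."""
    with open(path) as fh:
        symbols = fh.readline().strip().split(",")
        arr = AtomArray.from_symbols(symbols)
        n = len(symbols)
        idx = [(i, j) for i in range(n) for j in range(i)]
        out = []
        for line in fh:
            if not line.strip():
                continue
            vals = [int(x) for x in line.split(",")]
            B = np.zeros((n, n), dtype=np.int8)
            for (i, j), v in zip(idx, vals):
                B[i, j] = B[j, i] = v
            out.append(MolecularSystem(arr, B))
    return out
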