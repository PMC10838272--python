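"""Structural filters for enumerated and diversified products.

The funnel filter removes structures that are far from the amine-acid
substrates (> 6 bond edits) or heavily polycyclic (> 4 rings).  A separate
SMARTS-based filter removes strained ring motifs (bridgehead alkenes in
small bicyclics, in-ring triple bonds and cumulenes, stacked three-membered
rings); the pattern list is configuration, not chemistry the funnel counts
depend on, and ships as an editable module-level table.  Composition filters
(heavy-atom and heteroatom budgets, strict upper bounds) support virtual
library construction.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .canon import ProductRecord

__all__ = [
    "funnel_filter",
    "ring_count",
    "STRAINED_MOTIFS",
    "strained_motif_filter",
    "aromaticity_preserved",
    "composition_filter",
]


def ring_count(mol_or_smiles: str | Chem.Mol) -> int:
    """Number of rings (smallest set of smallest rings) of a molecule."""
    mol = (
        Chem.MolFromSmiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else mol_or_smiles
    )
    if mol is None:
        raise ValueError(f"could not parse {mol_or_smiles!r}")
    return rdMolDescriptors.CalcNumRings(mol)


def funnel_filter(
    records: Iterable[ProductRecord],
    max_rings: int = 4,
    max_edits: int = 6,
    log: Optional[list] = None,
) -> list[ProductRecord]:
    """Keep products with ring count <= max_rings and edit distance <= max_edits.

    Records missing a ``min_edit_distance`` are rejected with a log entry
    rather than guessed at.  Ring counts are computed from the canonical
    SMILES when not already cached in ``record.flags['rings']``.
    """
    out: list[ProductRecord] = []
    for rec in records:
        if rec.min_edit_distance is None:
            if log is not None:
                log.append((rec.smiles, "missing min_edit_distance"))
            continue
        rings = rec.flags.get("rings")
        if rings is None:
            rings = ring_count(rec.smiles)
            rec.flags["rings"] = rings
        if rings <= max_rings and rec.min_edit_distance <= max_edits:
            out.append(rec)
    return out


#: Strained-motif SMARTS patterns, editable configuration.  Each entry is
#: (name, SMARTS).  These are structural heuristics:
#:  - bridgehead_alkene: non-aromatic double bond from an atom with three
#:    ring bonds (a bridgehead) to one with two, inside rings of size <= 6
#:    (anti-Bredt).  Ring-fusion-edge alkenes, where both atoms carry three
#:    ring bonds, are accepted.
#:  - small_ring_triple: triple bond with an atom in a ring of size <= 7.
#:  - small_ring_cumulene: cumulated diene carbon inside a small ring.
#:  - fused_cyclopropane: two three-membered rings sharing an edge
#:    (bicyclobutane core).
#:  - spiro_cyclopropanes: an atom whose four ring neighbours all sit in
#:    three-membered rings (spiropentane core).
STRAINED_MOTIFS: list[tuple[str, str]] = [
    ("bridgehead_alkene", "[C;x3;!a;r3,r4,r5,r6]=[C;x2;!a]"),
    ("small_ring_triple", "[*;r3,r4,r5,r6,r7]#[*]"),
    ("small_ring_cumulene", "[*;R]=[C;r3,r4,r5,r6,r7]=[*;R]"),
    ("fused_cyclopropane", "[*]1[*]2[*][*]12"),
    ("spiro_cyclopropanes", "[C;R2](@[*;r3])(@[*;r3])(@[*;r3])@[*;r3]"),
]


def _compile_motifs(motifs: Sequence[tuple[str, str]]) -> list[tuple[str, Chem.Mol]]:
    out = []
    for name, smarts in motifs:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for motif {name!r}: {smarts}")
        out.append((name, patt))
    return out


_DEFAULT_COMPILED = None


def strained_motif_filter(
    mol: Chem.Mol | str,
    motifs: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[bool, Optional[str]]:
    """(passes, matched_motif_name): fail iff any strained pattern matches."""
    global _DEFAULT_COMPILED
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise ValueError("could not parse molecule")
    if motifs is None:
        if _DEFAULT_COMPILED is None:
            _DEFAULT_COMPILED = _compile_motifs(STRAINED_MOTIFS)
        compiled = _DEFAULT_COMPILED
    else:
        compiled = _compile_motifs(motifs)
    for name, patt in compiled:
        if mol.HasSubstructMatch(patt):
            return False, name
    return True, None


def aromaticity_preserved(substrate: Chem.Mol, product: Chem.Mol) -> bool:
    """True iff every aromatic ring of the substrate stays aromatic.

    The two molecules must share heavy-atom indexing (as they do along the
    diversification path, where products are edited copies of the substrate
    system).  An all-aliphatic substrate passes vacuously.
    """
    sub_info = substrate.GetRingInfo()
    prod_arom = {
        a.GetIdx() for a in product.GetAtoms() if a.GetIsAromatic()
    }
    for ring in sub_info.AtomRings():
        if all(substrate.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            if not all(i in prod_arom for i in ring):
                return False
    return True


def filter_report(
    records: Iterable[tuple[str, Chem.Mol | str]],
    motifs: Optional[Sequence[tuple[str, str]]] = None,
) -> "pd.DataFrame":
    """Per-record strain-filter report: id, filter name, pass/fail, motif."""
    import pandas as pd

    rows = []
    for rec_id, mol in records:
        ok, motif = strained_motif_filter(mol, motifs)
        rows.append(
            {
                "record_id": rec_id,
                "filter": "strained_motif",
                "passed": ok,
                "matched_motif": motif or "",
            }
        )
    return pd.DataFrame(rows, columns=["record_id", "filter", "passed", "matched_motif"])


def composition_filter(
    mols: Iterable[Chem.Mol | str],
    max_heavy: int = 13,
    max_NO: int = 2,
) -> list[Chem.Mol]:
    """Keep molecules with heavy atoms < max_heavy and N+O atoms < max_NO.

    Both bounds are strict, matching the library-construction convention
    ("less than 13 heavy atoms, less than two nitrogens and oxygens").
    """
    out = []
    for m in mols:
        mol = Chem.MolFromSmiles(m) if isinstance(m, str) else m
        if mol is None:
            continue
        heavy = mol.GetNumHeavyAtoms()
        n_no = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
        if heavy < max_heavy and n_no < max_NO:
            out.append(mol)
    return out
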