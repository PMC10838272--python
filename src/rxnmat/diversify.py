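"""Late-stage diversification: apply the enumerated transformation library
to substituted amine-acid substrate pairs.

The eight template atoms (amine N/alpha/beta, carboxyl C, both oxygens, acid
alpha/beta) are located on the substrate pair by substructure search, giving
a map from matrix row to substrate atom index.  Each transformation then
edits the mapped bond orders on an editable, kekulized copy of the combined
substrate molecule.  Because the library was enumerated for unsubstituted
carbons, many transformations over-bond a substituted carbon; those products
fail sanitization and are filtered out, categorized.  Optional predicates
reproduce the published workflow filters: strained-motif removal,
aromaticity retention for sp2 substrates, no-substituent-loss, and ring
retention at the reacting atoms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .filters import aromaticity_preserved, strained_motif_filter
from .reactions import (
    StartingMaterialTemplate,
    apply_transformation,
    starting_material_templates,
)

__all__ = [
    "map_template_atoms",
    "TemplateMapping",
    "diversify",
    "DiversifyResult",
    "generate_reaction_centers",
]

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

# Substructure patterns per hybridization, matched on the kekulized substrate
# so that aromatic alpha-beta bonds appear as explicit double bonds.
# Atom order in each SMARTS is documented next to the row assignment.
_AMINE_SMARTS = {
    "sp3": ("[NX3;H2][CX4][CX4]", (5, 1, 0)),  # N, alpha-C, beta-C
    "sp2": ("[NX3;H2][CX3]=[CX3]", (5, 1, 0)),
}
_ACID_SMARTS = {
    # OH, carboxyl C, =O, alpha-C, beta-C
    "sp3": ("[OX2H1][CX3](=[OX1])[CX4][CX4]", (7, 4, 6, 3, 2)),
    "sp2": ("[OX2H1][CX3](=[OX1])[CX3]=[CX3]", (7, 4, 6, 3, 2)),
}


@dataclass
class TemplateMapping:
    """Row-to-atom-index map of the 8 template rows onto a substrate pair."""

    template_id: str
    row_to_atom: dict[int, int]
    #: all (amine_match, acid_match) index tuples found; the first is used
    all_matches: list[tuple[tuple[int, ...], tuple[int, ...]]] = field(
        default_factory=list
    )

    @property
    def mapped_atoms(self) -> set[int]:
        return set(self.row_to_atom.values())


def _kekulized_copy(mol: Chem.Mol) -> Chem.Mol:
    m = Chem.Mol(mol)
    Chem.Kekulize(m, clearAromaticFlags=True)
    return m


def map_template_atoms(
    amine_smiles: str, acid_smiles: str, template_id: str = "sp3/sp3"
) -> tuple[Chem.Mol, TemplateMapping]:
    """Locate the template's eight atoms on a combined substrate pair.

    Returns the combined (sanitized, aromatic) substrate molecule and the
    mapping.  The pair must contain a primary amine and a carboxylic acid
    with the template's hybridization at the alpha/beta positions; a missing
    pattern raises ``ValueError("pattern not found ...")``.  When several
    chemically distinct matches exist, all are recorded and the first
    (RDKit canonical order) is used.
    """
    am_h, ac_h = template_id.split("/")
    combined = Chem.MolFromSmiles(amine_smiles + "." + acid_smiles)
    if combined is None:
        raise ValueError("could not parse substrate pair")
    kek = _kekulized_copy(combined)

    am_smarts, am_rows = _AMINE_SMARTS[am_h]
    ac_smarts, ac_rows = _ACID_SMARTS[ac_h]
    am_matches = kek.GetSubstructMatches(Chem.MolFromSmarts(am_smarts))
    ac_matches = kek.GetSubstructMatches(Chem.MolFromSmarts(ac_smarts))
    if not am_matches:
        raise ValueError(f"pattern not found: no {am_h} primary amine in pair")
    if not ac_matches:
        raise ValueError(f"pattern not found: no {ac_h} carboxylic acid in pair")

    pairs = [
        (am, ac)
        for am in am_matches
        for ac in ac_matches
        if not set(am) & set(ac)
    ]
    if not pairs:
        raise ValueError("pattern not found: amine and acid matches overlap")
    am, ac = pairs[0]
    row_to_atom = {row: am[k] for k, row in enumerate(am_rows)}
    row_to_atom.update({row: ac[k] for k, row in enumerate(ac_rows)})
    return combined, TemplateMapping(template_id, row_to_atom, pairs)


@dataclass
class DiversifyResult:
    """Products, aligned surviving indices and categorized rejections."""

    products: list[str]  # dot-separated SMILES of each surviving system
    surviving_indices: list[int]
    rejections: Counter
    mapping: TemplateMapping

    @property
    def n_total(self) -> int:
        return len(self.surviving_indices) + sum(self.rejections.values())


def _mapped_ring_sizes(mol: Chem.Mol, atoms: set[int]) -> dict[int, set[int]]:
    info = mol.GetRingInfo()
    sizes: dict[int, set[int]] = {a: set() for a in atoms}
    for ring in info.AtomRings():
        for a in ring:
            if a in atoms:
                sizes[a].add(len(ring))
    return sizes


def diversify(
    amine_smiles: str,
    acid_smiles: str,
    transformations: Iterable[np.ndarray],
    template_id: str = "sp3/sp3",
    keep_aromatic: bool = False,
    no_substituent_loss: bool = False,
    strained_filter: bool = False,
    ring_retention: Optional[int] = None,
) -> DiversifyResult:
    """Apply a transformation-matrix library to a substrate pair.

    ``transformations`` are signed 8x8 matrices on the template atom order.
    Every outcome is categorized: accepted plus all rejection categories
    partition the library.

    Rejection categories, in the order they are tested:
      ``negative_bond_order`` — an edit drives a mapped bond below zero;
      ``valence_violation`` — RDKit sanitization fails (octet breach at a
      substituted carbon, impossible kekulization, ...);
      ``aromaticity_broken`` — only with ``keep_aromatic``;
      ``substituent_loss`` — only with ``no_substituent_loss``: an unmapped
      heavy atom ends up in a different fragment than the others;
      ``ring_not_retained`` — only with ``ring_retention=k``: a mapped atom
      that sat in a k-ring of the substrate no longer does;
      ``strained_motif`` — only with ``strained_filter``.
    """
    substrate, mapping = map_template_atoms(amine_smiles, acid_smiles, template_id)
    base = _kekulized_copy(substrate)
    mapped = mapping.mapped_atoms
    sub_ring_sizes = (
        _mapped_ring_sizes(substrate, mapped) if ring_retention else {}
    )

    products: list[str] = []
    surviving: list[int] = []
    rejections: Counter = Counter()

    for idx, T in enumerate(transformations):
        T = np.asarray(T)
        rw = Chem.RWMol(base)
        bad: str | None = None
        for i in range(8):
            for j in range(i + 1, 8):
                if T[i, j] == 0:
                    continue
                ai, aj = mapping.row_to_atom[i], mapping.row_to_atom[j]
                bond = rw.GetBondBetweenAtoms(ai, aj)
                old = int(bond.GetBondTypeAsDouble()) if bond is not None else 0
                new = old + int(T[i, j])
                if new < 0:
                    bad = "negative_bond_order"
                    break
                if new > 3:  # beyond any representable bond order
                    bad = "valence_violation"
                    break
                if bond is not None and new == 0:
                    rw.RemoveBond(ai, aj)
                elif bond is not None:
                    bond.SetBondType(_BOND_TYPES[new])
                elif new > 0:
                    rw.AddBond(ai, aj, _BOND_TYPES[new])
            if bad:
                break
        if bad:
            rejections[bad] += 1
            continue
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            rejections["valence_violation"] += 1
            continue
        if keep_aromatic and not aromaticity_preserved(substrate, mol):
            rejections["aromaticity_broken"] += 1
            continue
        if no_substituent_loss:
            frags = Chem.GetMolFrags(mol)
            unmapped_frags = {
                fi
                for fi, frag in enumerate(frags)
                for a in frag
                if a not in mapped
            }
            if len(unmapped_frags) > 1:
                rejections["substituent_loss"] += 1
                continue
        if ring_retention:
            prod_sizes = _mapped_ring_sizes(mol, mapped)
            lost = any(
                ring_retention in sub_ring_sizes[a]
                and ring_retention not in prod_sizes[a]
                for a in mapped
            )
            if lost:
                rejections["ring_not_retained"] += 1
                continue
        if strained_filter:
            ok, motif = strained_motif_filter(mol)
            if not ok:
                rejections["strained_motif"] += 1
                continue
        products.append(Chem.MolToSmiles(mol))
        surviving.append(idx)

    return DiversifyResult(products, surviving, rejections, mapping)


def generate_reaction_centers(
    surviving_indices: Sequence[int],
    transformations: Sequence[np.ndarray],
    template: Optional[StartingMaterialTemplate] = None,
) -> list[str]:
    """Apply the surviving transformations to the simple amine-acid system.

    Returns one dot-separated SMILES per surviving index, order-aligned with
    the diversified products and deliberately not deduplicated: on the
    substituted substrate the alpha/beta carbons are distinct, so two centers
    that coincide on the simple system still represent different products.
    """
    if template is None:
        template = starting_material_templates()[0]
    centers: list[str] = []
    for idx in surviving_indices:
        result = apply_transformation(template.system, transformations[idx])
        if not result:
            raise ValueError(
                f"transformation {idx} valid on the substrate but not on the "
                f"simple system: {result.detail}"
            )
        centers.append(result.to_smiles())
    return centers
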