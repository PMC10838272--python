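"""Physicochemical descriptors and PMI shape coordinates.

Descriptor panel: hydrogen-bond donors/acceptors, molecular weight, topological
polar surface area, fraction of sp3 carbons, QED drug-likeness, Crippen logP,
rotatable bonds and ring count — the standard RDKit definitions throughout.

Shape analysis embeds each structure once in 3D (ETKDG distance geometry with
a fixed seed, hydrogens added), computes the three principal moments of
inertia sorted ascending and reports the normalized ratios
NPR1 = PMI1/PMI3, NPR2 = PMI2/PMI3.  Valid embeddings satisfy
NPR1 <= NPR2 <= 1 and NPR1 + NPR2 >= 1 (the rod-disc-sphere triangle);
embedding failure — which does happen for highly strained cages — is recorded
as a status, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Descriptors3D, QED, rdMolDescriptors

__all__ = [
    "PropertyRecord",
    "ShapeRecord",
    "compute_descriptors",
    "descriptor_table",
    "compute_npr",
    "npr_table",
    "property_deltas",
]


@dataclass(frozen=True)
class PropertyRecord:
    smiles: str
    HBD: int
    HBA: int
    MW: float
    PSA: float
    FSP3: float
    QED: float
    LogP: float
    ROTB: int
    rings: int
    #: variant with all-heavy-atom denominator (see module docs); not the default
    FSP3_heavy: float = 0.0


@dataclass(frozen=True)
class ShapeRecord:
    smiles: str
    NPR1: Optional[float]
    NPR2: Optional[float]
    embed_status: str  # "ok" | "failed" | "parse_error"


def compute_descriptors(smiles: str) -> PropertyRecord | None:
    """Full descriptor vector for one structure; None when unparsable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    n_heavy = mol.GetNumHeavyAtoms()
    sp3_c = sum(
        1
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetHybridization() == Chem.HybridizationType.SP3
    )
    return PropertyRecord(
        smiles=smiles,
        HBD=rdMolDescriptors.CalcNumHBD(mol),
        HBA=rdMolDescriptors.CalcNumHBA(mol),
        MW=Descriptors.MolWt(mol),
        PSA=rdMolDescriptors.CalcTPSA(mol),
        FSP3=rdMolDescriptors.CalcFractionCSP3(mol),
        QED=QED.qed(mol),
        LogP=Crippen.MolLogP(mol),
        ROTB=rdMolDescriptors.CalcNumRotatableBonds(mol),
        rings=rdMolDescriptors.CalcNumRings(mol),
        FSP3_heavy=sp3_c / n_heavy if n_heavy else 0.0,
    )


def descriptor_table(smiles_list: Iterable[str]) -> pd.DataFrame:
    """Descriptor panel as a DataFrame; unparsable entries are dropped with
    an ``error`` row marker rather than aborting the batch."""
    rows = []
    for smi in smiles_list:
        rec = compute_descriptors(smi)
        if rec is None:
            rows.append({"smiles": smi, "error": True})
        else:
            d = rec.__dict__.copy()
            d["error"] = False
            rows.append(d)
    return pd.DataFrame(rows)


def compute_npr(smiles: str, seed: int = 20) -> ShapeRecord:
    """Normalized PMI ratios from a single seeded ETKDG embedding."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return ShapeRecord(smiles, None, None, "parse_error")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    try:
        conf_id = AllChem.EmbedMolecule(molh, params)
    except Exception:
        conf_id = -1
    if conf_id < 0:
        return ShapeRecord(smiles, None, None, "failed")
    npr1 = Descriptors3D.NPR1(molh)
    npr2 = Descriptors3D.NPR2(molh)
    return ShapeRecord(smiles, npr1, npr2, "ok")


def npr_table(smiles_list: Iterable[str], seed: int = 20) -> pd.DataFrame:
    rows = [compute_npr(s, seed).__dict__ for s in smiles_list]
    return pd.DataFrame(rows, columns=["smiles", "NPR1", "NPR2", "embed_status"])


_DELTA_PROPS = ["HBD", "HBA", "MW", "PSA", "FSP3", "QED", "LogP", "ROTB", "rings"]


def property_deltas(
    substrate_products: pd.DataFrame,
    center_products: pd.DataFrame,
    reference_index: int,
) -> pd.DataFrame:
    """Per-transformation property shifts, whole molecule vs reaction center.

    Both inputs need a ``matrix_index`` column plus the descriptor panel;
    rows are paired on ``matrix_index``.  Every property is referenced to
    the row whose ``matrix_index`` equals ``reference_index`` (the classical
    amide transformation), giving the x/y coordinates of a
    whole-molecule-vs-center modulation plot.  Unpaired indices are dropped.
    """
    merged = substrate_products.merge(
        center_products, on="matrix_index", suffixes=("_mol", "_ctr")
    )
    ref = merged[merged["matrix_index"] == reference_index]
    if len(ref) != 1:
        raise ValueError(
            f"reference matrix_index {reference_index} matched {len(ref)} paired rows"
        )
    ref = ref.iloc[0]
    out = {"matrix_index": merged["matrix_index"]}
    for prop in _DELTA_PROPS:
        cm, cc = f"{prop}_mol", f"{prop}_ctr"
        if cm in merged and cc in merged:
            out[f"d{prop}_mol"] = merged[cm] - ref[cm]
            out[f"d{prop}_ctr"] = merged[cc] - ref[cc]
    return pd.DataFrame(out)
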