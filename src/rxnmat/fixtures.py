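"""Built-in fixtures: toy atom systems with oracle counts, a small synthetic
drug-like library, and worked reaction examples.

Everything here is generated in code (no data files), so every pipeline
stage is testable offline.  The drug library is a synthetic stand-in for a
licensed compound database: fifty well-known drug structures written out as
SMILES, enough to exercise substructure search, grouping and chord export.
"""

from __future__ import annotations

import numpy as np

from .elements import AtomArray
from .reactions import amide_transformation
from .system import MolecularSystem

__all__ = [
    "toy_systems",
    "toy_drug_library",
    "diels_alder_example",
    "cn_coupling_example",
    "worked_examples",
]


def toy_systems() -> dict[str, tuple[AtomArray, int]]:
    """Tiny atom arrays with independently verified matrix counts.

    The counts come from brute-force enumeration over every upper-triangle
    assignment (see ``brute_force_enumerate``), frozen here as oracle values:
    {C,O} has bond orders 0..2 (methane+water, methanol, formaldehyde);
    {C,N} adds the triple (HCN); {O,O} stops at the double bond.
    """
    return {
        "CO": (AtomArray.from_formula("C1O1"), 3),
        "CN": (AtomArray.from_formula("C1N1"), 4),
        "OO": (AtomArray.from_formula("O2"), 3),
        "CCO": (AtomArray.from_formula("C2O1"), 22),
        "CCNO": (AtomArray.from_formula("C2N1O1"), 219),
    }


def toy_drug_library() -> dict[str, str]:
    """Fifty drug structures as {name: SMILES} — a synthetic search library."""
    return {
        "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
        "paracetamol": "CC(=O)Nc1ccc(O)cc1",
        "ibuprofen": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
        "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
        "naproxen": "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
        "penicillin_g": "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",
        "amoxicillin": "CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O",
        "lidocaine": "CCN(CC)CC(=O)Nc1c(C)cccc1C",
        "procaine": "CCN(CC)CCOC(=O)c1ccc(N)cc1",
        "benzocaine": "CCOC(=O)c1ccc(N)cc1",
        "salbutamol": "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
        "atenolol": "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
        "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
        "metoprolol": "COCCc1ccc(OCC(O)CNC(C)C)cc1",
        "warfarin": "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
        "diazepam": "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O",
        "phenytoin": "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1",
        "phenobarbital": "CCC1(c2ccccc2)C(=O)NC(=O)NC1=O",
        "valproate": "CCCC(CCC)C(=O)O",
        "gabapentin": "NCC1(CC(=O)O)CCCCC1",
        "metformin": "CN(C)C(=N)NC(N)=N",
        "chlorpromazine": "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
        "fluoxetine": "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",
        "sertraline": "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21",
        "imipramine": "CN(C)CCCN1c2ccccc2CCc2ccccc21",
        "amitriptyline": "CN(C)CCC=C1c2ccccc2CCc2ccccc21",
        "morphine": "CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5",
        "codeine": "COc1ccc2CC3C4C=CC(O)C5Oc1c2C45CCN3C",
        "tramadol": "CN(C)CC1CCCCC1(O)c1cccc(OC)c1",
        "fentanyl": "CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
        "methadone": "CCC(=O)C(CC(C)N(C)C)(c1ccccc1)c1ccccc1",
        "nicotine": "CN1CCCC1c1cccnc1",
        "atropine": "CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2",
        "ketamine": "CNC1(c2ccccc2Cl)CCCCC1=O",
        "dopamine": "NCCc1ccc(O)c(O)c1",
        "adrenaline": "CNCC(O)c1ccc(O)c(O)c1",
        "serotonin": "NCCc1c[nH]c2ccc(O)cc12",
        "histamine": "NCCc1c[nH]cn1",
        "melatonin": "COc1ccc2[nH]cc(CCNC(C)=O)c2c1",
        "sulfanilamide": "Nc1ccc(S(N)(=O)=O)cc1",
        "isoniazid": "NNC(=O)c1ccncc1",
        "pyrazinamide": "NC(=O)c1cnccn1",
        "chloramphenicol": "O=C(NC(CO)C(O)c1ccc([N+](=O)[O-])cc1)C(Cl)Cl",
        "metronidazole": "Cc1ncc([N+](=O)[O-])n1CCO",
        "cimetidine": "CNC(=NC#N)NCCSCc1nc[nH]c1C",
        "ranitidine": "CNC(=CN(=O)=O)NCCSCc1ccc(CN(C)C)o1",
        "omeprazole": "COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1",
        "captopril": "CC(CS)C(=O)N1CCCC1C(=O)O",
        "enalapril": "CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O",
        "nifedipine": "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]",
    }


def diels_alder_example() -> tuple[MolecularSystem, MolecularSystem, np.ndarray]:
    """Butadiene + ethylene -> cyclohexene, encoded as a 6-carbon system.

    Returns (starting system, product system, transformation matrix).  The
    transformation has six unit bond edits: three pi bonds are downgraded
    and three sigma bonds formed.
    """
    arr = AtomArray.from_formula("C6")
    sm = np.zeros((6, 6), dtype=np.int8)
    prod = np.zeros((6, 6), dtype=np.int8)

    def setb(B, i, j, o):
        B[i, j] = B[j, i] = o

    # butadiene C0=C1-C2=C3, ethylene C4=C5
    setb(sm, 0, 1, 2)
    setb(sm, 1, 2, 1)
    setb(sm, 2, 3, 2)
    setb(sm, 4, 5, 2)
    # cyclohexene: ring with the former central bond now double
    setb(prod, 0, 1, 1)
    setb(prod, 1, 2, 2)
    setb(prod, 2, 3, 1)
    setb(prod, 3, 4, 1)
    setb(prod, 4, 5, 1)
    setb(prod, 5, 0, 1)
    sm_sys = MolecularSystem(arr, sm)
    prod_sys = MolecularSystem(arr, prod)
    return sm_sys, prod_sys, (prod - sm).astype(np.int8)


def cn_coupling_example() -> tuple[MolecularSystem, MolecularSystem, np.ndarray]:
    """Direct C-N coupling on a minimal {C,N} system: one bond edit."""
    arr = AtomArray.from_formula("C1N1")
    sm = np.zeros((2, 2), dtype=np.int8)
    prod = np.array([[0, 1], [1, 0]], dtype=np.int8)
    return MolecularSystem(arr, sm), MolecularSystem(arr, prod), (prod - sm)


def worked_examples() -> dict[str, dict]:
    """Named reaction examples with their expected bond edit distances."""
    da_sm, da_prod, da_T = diels_alder_example()
    cn_sm, cn_prod, cn_T = cn_coupling_example()
    return {
        "amide_coupling": {"T": amide_transformation(), "distance": 2},
        "diels_alder": {"sm": da_sm, "product": da_prod, "T": da_T, "distance": 6},
        "cn_coupling": {"sm": cn_sm, "product": cn_prod, "T": cn_T, "distance": 1},
    }
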