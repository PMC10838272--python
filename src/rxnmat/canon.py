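"""Degeneracy-aware deduplication of enumerated products.

Two bond matrices describe the same chemistry when one maps onto the other by
permuting chemically indistinguishable atoms — the two carboxylate oxygens,
or the unsubstituted carbons of the simple amine-acid system.  The
permutations allowed are exactly the products of symmetric groups on the
atom array's degeneracy classes.  Deduplication happens at two levels:

* matrix level: :func:`canonical_key` returns the lexicographically minimal
  upper triangle over the group, so two matrices share a key iff they are
  related by a degeneracy permutation.  :func:`count_orbits` obtains the
  orbit count without enumerating anything, via Burnside's lemma with a
  dynamic-programming count of group-invariant matrices.
* structure level: :func:`unique_products` converts matrices to molecules,
  splits multi-molecule systems into connected components, keeps components
  with at least ``min_heavy_atoms`` heavy atoms, and deduplicates by
  canonical SMILES (which also collapses any residual graph symmetry).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Optional

import numpy as np
from rdkit import Chem

from .elements import AtomArray
from .system import MolecularSystem, SanitizationError, matrix_to_mol

__all__ = [
    "degeneracy_group",
    "canonical_key",
    "canonical_matrix",
    "count_invariant_matrices",
    "count_orbits",
    "ProductRecord",
    "unique_products",
]


def degeneracy_group(atom_array: AtomArray) -> list[tuple[int, ...]]:
    """All atom permutations generated by the degeneracy classes.

    Returns full-length permutation tuples; atoms outside every class stay
    fixed.  The group order is the product of the class factorials.
    """
    n = len(atom_array)
    group: list[tuple[int, ...]] = []
    class_perms = [
        list(itertools.permutations(cls)) for cls in atom_array.degeneracy_classes
    ]
    for combo in itertools.product(*class_perms) if class_perms else [()]:
        perm = list(range(n))
        for cls, img in zip(atom_array.degeneracy_classes, combo):
            for src, dst in zip(cls, img):
                perm[src] = dst
        group.append(tuple(perm))
    return group


def _check_perm(perm, atom_array: AtomArray) -> None:
    for i, j in enumerate(perm):
        if atom_array.atoms[i] != atom_array.atoms[j]:
            raise ValueError(
                f"permutation maps atom {i} ({atom_array.symbols[i]}) onto atom "
                f"{j} ({atom_array.symbols[j]}): crosses element types"
            )


def canonical_matrix(
    B: np.ndarray,
    atom_array: AtomArray,
    group: Optional[Iterable[tuple[int, ...]]] = None,
) -> np.ndarray:
    """Lexicographically minimal matrix over the degeneracy group."""
    B = np.asarray(B, dtype=np.int8)
    if group is None:
        group = degeneracy_group(atom_array)
    n = B.shape[0]
    iu = np.triu_indices(n, k=1)
    best = None
    best_key = None
    for perm in group:
        _check_perm(perm, atom_array)
        p = np.asarray(perm)
        Bp = B[np.ix_(p, p)]
        key = Bp[iu].tobytes()
        if best_key is None or key < best_key:
            best_key, best = key, Bp
    return best


def canonical_key(
    B: np.ndarray,
    atom_array: AtomArray,
    group: Optional[Iterable[tuple[int, ...]]] = None,
) -> bytes:
    """Upper-triangle bytes of :func:`canonical_matrix` — an orbit invariant."""
    n = np.asarray(B).shape[0]
    iu = np.triu_indices(n, k=1)
    return canonical_matrix(B, atom_array, group)[iu].tobytes()


def count_invariant_matrices(atom_array: AtomArray, perm: tuple[int, ...]) -> int:
    """Number of valid matrices fixed by one atom permutation.

    A fixed matrix is constant on each orbit of the permutation acting on
    unordered atom pairs, and consumes row capacity identically within each
    atom cycle; this reduces the count to a small memoized recursion over
    pair orbits with one capacity per atom cycle.
    """
    n = len(atom_array)
    t, b = atom_array.t, atom_array.b
    _check_perm(perm, atom_array)

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    seen: set[tuple[int, int]] = set()
    orbits: list[list[tuple[int, int]]] = []
    for p in pairs:
        if p in seen:
            continue
        orb: list[tuple[int, int]] = []
        q = p
        while q not in seen:
            seen.add(q)
            orb.append(q)
            a, c = perm[q[0]], perm[q[1]]
            q = (a, c) if a < c else (c, a)
        orbits.append(orb)

    cycles: list[list[int]] = []
    aseen: set[int] = set()
    for i in range(n):
        if i in aseen:
            continue
        cyc = [i]
        j = perm[i]
        while j != i:
            cyc.append(j)
            j = perm[j]
        cycles.append(cyc)
        aseen.update(cyc)
    cyc_of = {i: k for k, cyc in enumerate(cycles) for i in cyc}

    orb_info: list[tuple[int, tuple[tuple[int, int], ...]]] = []
    for orb in orbits:
        i0, j0 = orb[0]
        cap = min(b[i0], b[j0])
        deg: dict[int, int] = {}
        for i, j in orb:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
        cdeg: dict[int, int] = {}
        for i, d in deg.items():
            k = cyc_of[i]
            assert cdeg.setdefault(k, d) == d, "unequal degree within a cycle"
        orb_info.append((cap, tuple(sorted(cdeg.items()))))

    caps0 = tuple(t[cyc[0]] for cyc in cycles)

    @lru_cache(maxsize=None)
    def rec(k: int, caps: tuple[int, ...]) -> int:
        if k == len(orb_info):
            return 1
        cap, cdeg = orb_info[k]
        emax = cap
        for ck, d in cdeg:
            emax = min(emax, caps[ck] // d)
        total = 0
        for e in range(emax + 1):
            nc = list(caps)
            for ck, d in cdeg:
                nc[ck] -= e * d
            total += rec(k + 1, tuple(nc))
        return total

    return rec(0, caps0)


def count_orbits(atom_array: AtomArray) -> int:
    """Number of matrix orbits under the degeneracy group (Burnside).

    orbits = (1/|G|) * sum over g in G of #matrices fixed by g.  Exact and
    fast even for the full 8-atom system, where the 240-element carbon/oxygen
    group reduces 55,964,558 matrices to 282,658 orbits.
    """
    group = degeneracy_group(atom_array)
    total = sum(count_invariant_matrices(atom_array, g) for g in group)
    assert total % len(group) == 0
    return total // len(group)


@dataclass
class ProductRecord:
    """One unique product structure with provenance."""

    smiles: str
    n_heavy_atoms: int
    min_edit_distance: Optional[int] = None
    #: first-encountered matrix (stream order) that produced this structure
    witness: Optional[np.ndarray] = None
    flags: dict = field(default_factory=dict)


def unique_products(
    stream: Iterable[MolecularSystem | np.ndarray],
    atom_array: Optional[AtomArray] = None,
    min_heavy_atoms: int = 4,
    mode: str = "component",
    distances: Optional[Iterable[int]] = None,
    log: Optional[list] = None,
) -> dict[str, ProductRecord]:
    """Unique canonical structures from a matrix stream.

    Each matrix is decoded to molecule(s); in ``component`` mode (default)
    multi-molecule systems are split and each connected component with at
    least ``min_heavy_atoms`` heavy atoms counts as a product; in
    ``whole-system`` mode the heavy-atom threshold applies to the entire
    system and the dot-separated SMILES is the key.  Canonical SMILES is the
    uniqueness key, so oxygen and unsubstituted-carbon degeneracy collapse
    automatically (all routes to butane become one record).  Sanitization
    failures are logged to ``log`` and skipped, never raised.

    When ``distances`` is given (aligned with the stream), each record keeps
    the minimum distance over all matrices that produced it.
    """
    if mode not in ("component", "whole-system"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, ProductRecord] = {}
    dist_iter = iter(distances) if distances is not None else None
    for item in stream:
        if isinstance(item, MolecularSystem):
            B, arr = item.B, item.atom_array
        else:
            B, arr = np.asarray(item, dtype=np.int8), atom_array
            if arr is None:
                raise ValueError("atom_array required when streaming raw matrices")
        d = next(dist_iter) if dist_iter is not None else None
        try:
            mol = matrix_to_mol(B, arr)
        except SanitizationError as exc:
            if log is not None:
                log.append((B.copy(), str(exc)))
            continue
        if mode == "whole-system":
            parts = [mol] if mol.GetNumAtoms() >= min_heavy_atoms else []
        else:
            parts = [
                f
                for f in Chem.GetMolFrags(mol, asMols=True)
                if f.GetNumAtoms() >= min_heavy_atoms
            ]
        for part in parts:
            smi = Chem.MolToSmiles(part)
            rec = out.get(smi)
            if rec is None:
                out[smi] = ProductRecord(
                    smiles=smi,
                    n_heavy_atoms=part.GetNumAtoms(),
                    min_edit_distance=d,
                    witness=B.copy(),
                )
            elif d is not None and (
                rec.min_edit_distance is None or d < rec.min_edit_distance
            ):
                rec.min_edit_distance = d
    return out
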