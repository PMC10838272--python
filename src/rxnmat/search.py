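"""Substructure-frequency search of enumerated products against a library.

Each enumerated product is used as a query against every library compound;
the frequency is the number of symmetry-distinct embeddings (distinct atom
sets, so automorphic re-matches of the same atoms count once).  With
``preserve_aromaticity=True`` (default) both sides keep their perceived
aromaticity, so an aliphatic query bond never matches an aromatic ring bond
— avoiding matches whose retrosynthetic reading would fragment an aromatic
ring.  With ``preserve_aromaticity=False`` both sides are kekulized and the
query's explicit single/double pattern is matched against the kekule
structure.

Results feed two exports: an elemental-composition grouping (C only, C+N,
C+O, C+N+O) with top-k motifs per group, and a chord-diagram data table with
queries ordered by bond edit distance from the amine-acid substrates.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd
from rdkit import Chem

__all__ = [
    "substructure_frequencies",
    "group_by_composition",
    "chord_export",
]


def _prepare(smiles: str, preserve_aromaticity: bool) -> Optional[Chem.Mol]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if not preserve_aromaticity:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def substructure_frequencies(
    queries: Iterable[str],
    library: Mapping[str, str] | Iterable[str],
    preserve_aromaticity: bool = True,
    log: Optional[list] = None,
) -> pd.DataFrame:
    """Match counts for every (query, compound) pair with a nonzero count.

    ``library`` maps compound ids to SMILES (a plain iterable of SMILES uses
    the strings themselves as ids).  Returns a DataFrame with columns
    ``query``, ``compound``, ``count`` plus a per-query ``total`` obtainable
    by groupby; unparsable entries go to ``log`` and are skipped.
    """
    if not isinstance(library, Mapping):
        library = {s: s for s in library}
    lib_mols: list[tuple[str, Chem.Mol]] = []
    for cid, smi in library.items():
        mol = _prepare(smi, preserve_aromaticity)
        if mol is None:
            if log is not None:
                log.append(("library", cid, smi))
            continue
        lib_mols.append((cid, mol))

    rows = []
    for q in queries:
        qmol = _prepare(q, preserve_aromaticity)
        if qmol is None:
            if log is not None:
                log.append(("query", q, q))
            continue
        for cid, mol in lib_mols:
            matches = mol.GetSubstructMatches(qmol, uniquify=True, maxMatches=100000)
            distinct = {frozenset(m) for m in matches}
            if distinct:
                rows.append({"query": q, "compound": cid, "count": len(distinct)})
    return pd.DataFrame(rows, columns=["query", "compound", "count"])


def _composition_group(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    elems = {a.GetSymbol() for a in mol.GetAtoms()}
    has_n, has_o = "N" in elems, "O" in elems
    if has_n and has_o:
        return "C+N+O"
    if has_n:
        return "C+N"
    if has_o:
        return "C+O"
    return "C only"


def group_by_composition(
    freq_table: pd.DataFrame, top_k: int = 3, top_overall: int = 100
) -> pd.DataFrame:
    """Rank queries by total frequency within elemental-composition groups.

    The ``top_overall`` most frequent queries are grouped into
    {C only, C+N, C+O, C+N+O} and the ``top_k`` per group returned, with
    columns ``group``, ``rank``, ``query``, ``total``.
    """
    if freq_table.empty:
        return pd.DataFrame(columns=["group", "rank", "query", "total"])
    totals = (
        freq_table.groupby("query")["count"]
        .sum()
        .sort_values(ascending=False)
        .head(top_overall)
    )
    df = totals.reset_index().rename(columns={"count": "total"})
    df["group"] = df["query"].map(_composition_group)
    df["rank"] = df.groupby("group")["total"].rank(
        method="first", ascending=False
    ).astype(int)
    out = df[df["rank"] <= top_k].sort_values(["group", "rank"])
    return out[["group", "rank", "query", "total"]].reset_index(drop=True)


def _frequency_band(count: int) -> str:
    if count <= 1:
        return "1"
    if count <= 10:
        return "2-10"
    return ">10"


def chord_export(
    freq_table: pd.DataFrame,
    edit_distances: Mapping[str, int],
    path: Optional[str] = None,
) -> pd.DataFrame:
    """Chord-diagram link table: nonzero (compound, query) links with
    frequency bands, queries sorted by ascending bond edit distance from the
    amine-acid starting materials (ties broken by canonical SMILES).

    Every query must have an entry in ``edit_distances``.  When ``path`` is
    given the table is also written as TSV.
    """
    cols = ["query", "compound", "count", "edit_distance", "band", "query_position"]
    if freq_table.empty:
        out = pd.DataFrame(columns=cols)
    else:
        missing = set(freq_table["query"]) - set(edit_distances)
        if missing:
            raise ValueError(f"queries missing edit distances: {sorted(missing)[:5]}")
        df = freq_table[freq_table["count"] > 0].copy()
        df["edit_distance"] = df["query"].map(edit_distances)
        df["band"] = df["count"].map(_frequency_band)
        order = sorted(
            df["query"].unique(), key=lambda q: (edit_distances[q], q)
        )
        pos = {q: k for k, q in enumerate(order)}
        df["query_position"] = df["query"].map(pos)
        out = df.sort_values(["query_position", "compound"]).reset_index(drop=True)[cols]
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out
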