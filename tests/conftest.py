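import itertools

import numpy as np
import pytest

from rxnmat import amine_acid_array, starting_material_templates
from rxnmat.elements import AtomArray


@pytest.fixture(scope="session")
def templates():
    return starting_material_templates()


@pytest.fixture(scope="session")
def aa_array():
    return amine_acid_array()


def multisets_upto(max_size: int):
    """All atom multisets over {C,N,O} with 1..max_size atoms."""
    out = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations_with_replacement("CNO", size):
            out.append("".join(combo))
    return out


def vectorized_brute_count(atom_array: AtomArray) -> tuple[int, set]:
    """Independent oracle: enumerate every upper-triangle assignment with
    numpy and keep the valid ones.  Returns (count, set of entry tuples)."""
    n = len(atom_array)
    t = np.asarray(atom_array.t)
    b = np.asarray(atom_array.b)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if not pairs:
        return 1, {()}
    maxb = int(b.max())
    grids = np.meshgrid(*[np.arange(maxb + 1)] * len(pairs), indexing="ij")
    assign = np.stack([g.ravel() for g in grids], axis=1).astype(np.int8)
    ok = np.ones(len(assign), dtype=bool)
    rowsum = np.zeros((len(assign), n), dtype=np.int16)
    for k, (i, j) in enumerate(pairs):
        ok &= assign[:, k] <= min(b[i], b[j])
        rowsum[:, i] += assign[:, k]
        rowsum[:, j] += assign[:, k]
    ok &= (rowsum <= t[None, :]).all(axis=1)
    valid = assign[ok]
    return len(valid), {tuple(int(x) for x in row) for row in valid}
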