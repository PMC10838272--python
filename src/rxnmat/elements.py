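"""Per-element bonding parameters and ordered atom arrays.

Every heavy atom is described by two integers: ``t``, the maximum total bond
order the neutral atom may carry to other heavy atoms plus implicit hydrogens,
and ``b``, the highest order allowed for any single bond from it.  Neutral
carbon is (4, 3) — tetravalent but no quadruple bonds — nitrogen (3, 3) and
oxygen (2, 2).  Formal charges are never represented, which is what pins the
oxygen caps: a neutral oxygen with a triple bond would require a charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class ElementSpec:
    """Bonding caps for one neutral element.

    Parameters
    ----------
    symbol : str
        Element symbol, e.g. ``"C"``.
    t : int
        Maximum total bond order originating from the atom.
    b : int
        Maximum order of any individual bond.
    """

    symbol: str
    t: int
    b: int

    def __post_init__(self) -> None:
        if not (1 <= self.b <= self.t):
            raise ValueError(
                f"ElementSpec({self.symbol}): need 1 <= b <= t, got t={self.t}, b={self.b}"
            )


#: Default caps for the neutral elements handled out of the box.
DEFAULT_SPECS: dict[str, ElementSpec] = {
    "C": ElementSpec("C", 4, 3),
    "N": ElementSpec("N", 3, 3),
    "O": ElementSpec("O", 2, 2),
}


def spec_for(symbol: str) -> ElementSpec:
    """Look up the default :class:`ElementSpec` for an element symbol."""
    try:
        return DEFAULT_SPECS[symbol]
    except KeyError:
        raise ValueError(
            f"no bonding parameters registered for element {symbol!r}; "
            f"supported: {sorted(DEFAULT_SPECS)}"
        ) from None


@dataclass(frozen=True)
class AtomArray:
    """Ordered list of atoms plus a partition into interchangeable classes.

    ``degeneracy_classes`` partitions atom indices into groups that are
    chemically indistinguishable (e.g. the two carboxylate oxygens, or the
    unsubstituted carbons of the simple amine-acid system).  Atoms in one
    class must share an :class:`ElementSpec`.
    """

    atoms: tuple[ElementSpec, ...]
    degeneracy_classes: tuple[tuple[int, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for cls in self.degeneracy_classes:
            for i in cls:
                if not 0 <= i < len(self.atoms):
                    raise ValueError(f"degeneracy class index {i} out of range")
                if i in seen:
                    raise ValueError(f"atom {i} appears in two degeneracy classes")
                seen.add(i)
            if len({self.atoms[i] for i in cls}) > 1:
                raise ValueError(
                    f"degeneracy class {cls} mixes different element specs"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(a.symbol for a in self.atoms)

    @property
    def t(self) -> tuple[int, ...]:
        return tuple(a.t for a in self.atoms)

    @property
    def b(self) -> tuple[int, ...]:
        return tuple(a.b for a in self.atoms)

    @classmethod
    def from_symbols(
        cls,
        symbols: Sequence[str],
        degeneracy_classes: Sequence[Sequence[int]] = (),
    ) -> "AtomArray":
        return cls(
            atoms=tuple(spec_for(s) for s in symbols),
            degeneracy_classes=tuple(tuple(c) for c in degeneracy_classes),
        )

    @classmethod
    def from_formula(cls, formula: str) -> "AtomArray":
        """Parse a compact multiset formula like ``"C5N1O2"``.

        Atoms are laid out element-by-element in the order written; each
        element's atoms form one degeneracy class.
        """
        import re

        symbols: list[str] = []
        classes: list[tuple[int, ...]] = []
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
            if not m.group(0):
                continue
            sym, cnt = m.group(1), int(m.group(2) or 1)
            start = len(symbols)
            symbols.extend([sym] * cnt)
            classes.append(tuple(range(start, start + cnt)))
        if "".join(f"{s}" for s in symbols) == "":
            raise ValueError(f"could not parse formula {formula!r}")
        return cls.from_symbols(symbols, classes)


# Atom ordering convention for the 8-atom amine-acid system
# (index: role):
#   0  amine beta-carbon      1  amine alpha-carbon
#   2  acid beta-carbon       3  acid alpha-carbon
#   4  carboxyl carbon        5  amine nitrogen
#   6  carboxyl oxygen (C=O)  7  hydroxyl oxygen (C-OH)
# All results are invariant to this choice; it only fixes matrix layout.
AMINE_ACID_SYMBOLS = ("C", "C", "C", "C", "C", "N", "O", "O")

#: Degeneracy classes of the unsubstituted system: all five carbons carry only
#: hydrogens and are interchangeable, as are the two oxygens.
AMINE_ACID_DEGENERACY = ((0, 1, 2, 3, 4), (6, 7))


def amine_acid_array(full_degeneracy: bool = True) -> AtomArray:
    """The default 8-atom amine-acid atom array (5 C, 1 N, 2 O).

    With ``full_degeneracy=False`` only the two oxygens are marked
    interchangeable, which is the appropriate setting when the carbons carry
    distinct substituents.
    """
    classes = AMINE_ACID_DEGENERACY if full_degeneracy else ((6, 7),)
    return AtomArray.from_symbols(AMINE_ACID_SYMBOLS, classes)
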