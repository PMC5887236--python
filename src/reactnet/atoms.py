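"""Atom bookkeeping for connectivity-matrix states.

A state in the hypothetical chemical space is a symmetric 0/1 atom-connectivity
(AC) matrix over an *ordered* atom list.  Atom indices are stable for the
lifetime of a run: the reactant input fixes the order, and every enumerated
intermediate, the designated product, and every network vertex live on the
same basis.  Atoms carry two user flags: ``active`` marks reaction-center
atoms (enumeration operates on the sub-matrix over these), and ``catalyst``
marks atoms whose involvement is required for a network edge in catalytic
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Ti": 22, "Cr": 24,
    "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30, "Br": 35,
    "Ru": 44, "Rh": 45, "Pd": 46, "Ag": 47, "I": 53, "Pt": 78, "Au": 79,
}

#: covalent radii in Angstrom (Cordero-style values) used for XYZ bond perception
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "K": 2.03, "Ca": 1.76, "Ti": 1.60, "Cr": 1.39, "Mn": 1.39,
    "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22, "Br": 1.20,
    "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "I": 1.39, "Pt": 1.36,
}

#: elements handled by coordination-number rules instead of the octet valence model
METALS = frozenset({
    "Li", "Na", "K", "Mg", "Ca", "Al", "Ti", "Cr", "Mn", "Fe", "Co", "Ni",
    "Cu", "Zn", "Ru", "Rh", "Pd", "Ag", "Pt", "Au",
})


class UnknownElementError(ValueError):
    """Raised for element symbols outside the supported tables."""


def atomic_number(symbol: str) -> int:
    try:
        return ATOMIC_NUMBERS[symbol]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None


@dataclass(frozen=True)
class Atom:
    """One entry of an ordered atom list."""

    symbol: str
    index: int
    active: bool = True
    catalyst: bool = False

    @property
    def z(self) -> int:
        return atomic_number(self.symbol)


class AtomList(Sequence):
    """Ordered, immutable list of atoms shared by all states of a run."""

    def __init__(self, atoms: Iterable[Atom]):
        self._atoms = tuple(atoms)
        if not self._atoms:
            raise ValueError("atom list must be nonempty")
        for i, a in enumerate(self._atoms):
            if a.index != i:
                raise ValueError(f"atom {i} carries index {a.index}; indices must match positions")
        self.symbols = tuple(a.symbol for a in self._atoms)
        self.z = np.array([a.z for a in self._atoms], dtype=float)

    @classmethod
    def from_symbols(
        cls,
        symbols: Sequence[str],
        active: Iterable[int] | None = None,
        catalyst: Iterable[int] | None = None,
    ) -> "AtomList":
        """Build an atom list from element symbols.

        ``active`` is a set of 0-based indices; ``None`` flags every atom
        active (all-atom enumeration).  ``catalyst`` defaults to none.
        """
        n = len(symbols)
        act = set(range(n)) if active is None else set(active)
        cat = set() if catalyst is None else set(catalyst)
        for idx in act | cat:
            if not (0 <= idx < n):
                raise IndexError(f"atom index {idx} outside 0..{n - 1}")
        return cls(
            Atom(sym, i, active=(i in act), catalyst=(i in cat))
            for i, sym in enumerate(symbols)
        )

    def __len__(self) -> int:
        return len(self._atoms)

    def __getitem__(self, i):
        return self._atoms[i]

    def __iter__(self) -> Iterator[Atom]:
        return iter(self._atoms)

    def __eq__(self, other) -> bool:
        return isinstance(other, AtomList) and self._atoms == other._atoms

    def __hash__(self) -> int:
        return hash(self._atoms)

    @property
    def active_indices(self) -> tuple[int, ...]:
        return tuple(a.index for a in self._atoms if a.active)

    @property
    def catalyst_indices(self) -> tuple[int, ...]:
        return tuple(a.index for a in self._atoms if a.catalyst)

    def element_classes(self) -> dict[str, tuple[int, ...]]:
        """Indices grouped by element symbol (the permutable classes)."""
        classes: dict[str, list[int]] = {}
        for a in self._atoms:
            classes.setdefault(a.symbol, []).append(a.index)
        return {sym: tuple(ix) for sym, ix in classes.items()}

    def with_flags(
        self,
        active: Iterable[int] | None = None,
        catalyst: Iterable[int] | None = None,
    ) -> "AtomList":
        """Copy with new active/catalyst flag sets (None keeps current flags)."""
        act = set(self.active_indices) if active is None else set(active)
        cat = set(self.catalyst_indices) if catalyst is None else set(catalyst)
        return AtomList(
            replace(a, active=(a.index in act), catalyst=(a.index in cat))
            for a in self._atoms
        )

    def subset(self, indices: Sequence[int]) -> "AtomList":
        """Atom list restricted to ``indices`` (re-indexed from 0)."""
        return AtomList(
            replace(self._atoms[j], index=i) for i, j in enumerate(indices)
        )
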