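"""Built-in reference systems.

Three reaction systems ship with the package:

``halogen_exchange``
    2 ICl + H2 -> 2 HCl + I2, the six-atom worked example.  Small enough
    for exhaustive oracles: every state, conversion and distance can be
    verified by brute force.

``claisen``
    Claisen ester condensation: two ethyl acetate molecules and an ethoxide
    base condense to ethyl acetoacetate, ethanol and a regenerated
    ethoxide.  Eight active atoms cover the accepted mechanism
    (alpha-deprotonation, C-C attack on the second ester's carbonyl,
    ethoxide expulsion).

``hydroformylation``
    HCo(CO)3-catalyzed hydroformylation of ethylene with CO/H2 to
    propanal.  Eight active atoms (hydride, Co, both olefin carbons, the
    incoming CO, both H2 atoms); Co is the catalyst atom, so network edges
    must involve it.  Ring bound 1 admits the three-membered
    metal-olefin coordination motif.

Active-atom choices are this package's reading of the reaction centers;
the stored regression numbers are advisory expectations used by the
``--strict`` pipeline flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atoms import AtomList

Pair = tuple[int, int]


def _matrix(n: int, bonds: tuple[Pair, ...]) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in bonds:
        a[i, j] = a[j, i] = 1
    return a


@dataclass(frozen=True)
class Fixture:
    """A reactant/product system with its run settings."""

    name: str
    symbols: tuple[str, ...]
    reactant_bonds: tuple[Pair, ...]
    formed: tuple[Pair, ...]          # product bonds absent in the reactant
    broken: tuple[Pair, ...]          # reactant bonds absent in the product
    active: tuple[int, ...] | None
    catalyst: tuple[int, ...]
    charge: int
    ring_bounds: tuple[int, int | None]
    reactant_smiles: str
    product_smiles: str
    #: elementary steps (formed, broken) of the accepted mechanism, from R
    mechanism: tuple[tuple[tuple[Pair, ...], tuple[Pair, ...]], ...] = ()
    #: advisory regression numbers (enforced only under --strict)
    expected: dict = field(default_factory=dict)

    def atom_list(self) -> AtomList:
        return AtomList.from_symbols(self.symbols, active=self.active, catalyst=self.catalyst)

    def reactant_matrix(self) -> np.ndarray:
        return _matrix(len(self.symbols), self.reactant_bonds)

    def product_matrix(self) -> np.ndarray:
        a = self.reactant_matrix()
        for i, j in self.broken:
            a[i, j] = a[j, i] = 0
        for i, j in self.formed:
            a[i, j] = a[j, i] = 1
        return a

    def mechanism_matrices(self) -> list[np.ndarray]:
        """State sequence R, I1, ..., P along the accepted mechanism."""
        seq = [self.reactant_matrix()]
        for formed, broken in self.mechanism:
            a = seq[-1].copy()
            for i, j in broken:
                a[i, j] = a[j, i] = 0
            for i, j in formed:
                a[i, j] = a[j, i] = 1
            seq.append(a)
        return seq


HALOGEN_EXCHANGE = Fixture(
    name="halogen_exchange",
    # 0:I 1:Cl of one ICl, 2:I 3:Cl of the other, 4:H 5:H
    symbols=("I", "Cl", "I", "Cl", "H", "H"),
    reactant_bonds=((0, 1), (2, 3), (4, 5)),
    formed=((0, 2), (1, 5), (3, 4)),
    broken=((0, 1), (2, 3), (4, 5)),
    active=None,  # all six atoms react
    catalyst=(),
    charge=0,
    ring_bounds=(0, 0),
    reactant_smiles="ICl.ICl.[H][H]",
    product_smiles="Cl.Cl.II",
    mechanism=(
        # 2 ICl + H2 -> HI + HCl + ICl
        (((0, 4), (1, 5)), ((0, 1), (4, 5))),
        # HI + HCl + ICl -> I2 + 2 HCl
        (((0, 2), (3, 4)), ((0, 4), (2, 3))),
    ),
    expected={"cd_rp": 6},
)


_CLAISEN_SYMBOLS = (
    # ester A: 0 C(alpha) 1 C(carbonyl) 2 O(carbonyl) 3 O(ester) 4 C(H2) 5 C(H3)
    "C", "C", "O", "O", "C", "C",
    # ester B: 6 C(alpha) 7 C(carbonyl) 8 O(carbonyl) 9 O(ester) 10 C(H2) 11 C(H3)
    "C", "C", "O", "O", "C", "C",
    # ethoxide: 12 O(-) 13 C(H2) 14 C(H3)
    "O", "C", "C",
    # hydrogens 15..35
    "H", "H", "H",          # on 0 (alpha A)
    "H", "H",               # on 4
    "H", "H", "H",          # on 5
    "H", "H", "H",          # on 6 (alpha B)
    "H", "H",               # on 10
    "H", "H", "H",          # on 11
    "H", "H",               # on 13
    "H", "H", "H",          # on 14
)

_CLAISEN_BONDS = (
    (0, 1), (1, 2), (1, 3), (3, 4), (4, 5),
    (6, 7), (7, 8), (7, 9), (9, 10), (10, 11),
    (12, 13), (13, 14),
    (0, 15), (0, 16), (0, 17),
    (4, 18), (4, 19),
    (5, 20), (5, 21), (5, 22),
    (6, 23), (6, 24), (6, 25),
    (10, 26), (10, 27),
    (11, 28), (11, 29), (11, 30),
    (13, 31), (13, 32),
    (14, 33), (14, 34), (14, 35),
)

CLAISEN = Fixture(
    name="claisen",
    symbols=_CLAISEN_SYMBOLS,
    reactant_bonds=_CLAISEN_BONDS,
    formed=((12, 15), (0, 7)),
    broken=((0, 15), (7, 9)),
    # reaction centers: every atom that changes bonds or carries charge in
    # the accepted mechanism: alpha H + alpha C + enolate O of ester A,
    # carbonyl C/O + leaving ester O of ester B, ethoxide O
    active=(0, 2, 7, 8, 9, 12, 15),
    catalyst=(),
    charge=-1,
    ring_bounds=(0, 0),
    reactant_smiles="CC(=O)OCC.CC(=O)OCC.CC[O-]",
    product_smiles="CCOC(=O)CC(C)=O.CCO.CC[O-]",
    mechanism=(
        # deprotonation: enolate + ethanol
        (((12, 15),), ((0, 15),)),
        # C-C attack: tetrahedral alkoxide
        (((0, 7),), ()),
        # ethoxide expulsion: ethyl acetoacetate
        ((), ((7, 9),)),
    ),
    expected={
        "cd_rp": 4,
        "intermediates": 113,
        "after_energy": 66,
        "after_ellipse": 32,
        "network_edges": 376,
        "kept_paths": 29,
        "minimal_vertices": 14,
        "minimal_edges": 35,
    },
)


_HYDROFORMYLATION_SYMBOLS = (
    # 0 Co, 1 H(hydride), three carbonyl ligands (2,3) (4,5) (6,7)
    "Co", "H", "C", "O", "C", "O", "C", "O",
    # ethylene: 8 C 9 C with H 10..13
    "C", "C", "H", "H", "H", "H",
    # free CO: 14 C 15 O
    "C", "O",
    # H2: 16 17
    "H", "H",
)

_HYDROFORMYLATION_BONDS = (
    (0, 1), (0, 2), (2, 3), (0, 4), (4, 5), (0, 6), (6, 7),
    (8, 9), (8, 10), (8, 11), (9, 12), (9, 13),
    (14, 15),
    (16, 17),
)

HYDROFORMYLATION = Fixture(
    name="hydroformylation",
    symbols=_HYDROFORMYLATION_SYMBOLS,
    reactant_bonds=_HYDROFORMYLATION_BONDS,
    formed=((1, 8), (9, 14), (14, 16), (0, 17)),
    broken=((0, 1), (16, 17)),
    # hydride, Co, both olefin carbons, incoming CO, both H2 atoms
    active=(0, 1, 8, 9, 14, 15, 16, 17),
    catalyst=(0,),
    charge=0,
    ring_bounds=(0, 1),
    reactant_smiles="[H][Co](C#O)(C#O)C#O.C=C.[C-]#[O+].[H][H]",
    product_smiles="CCC=O.[H][Co](C#O)(C#O)C#O",
    mechanism=(
        # olefin coordination
        (((0, 8), (0, 9)), ()),
        # hydride migration: ethyl complex
        (((1, 8),), ((0, 1), (0, 8))),
        # CO coordination
        (((0, 14),), ()),
        # migratory insertion: acyl complex
        (((9, 14),), ((0, 9),)),
        # hydrogenolysis: propanal + regenerated catalyst
        (((14, 16), (0, 17)), ((16, 17), (0, 14))),
    ),
    expected={
        "cd_rp": 6,
        "intermediates": 239,
        "after_energy": 224,
        "after_ellipse": 54,
        "network_edges": 403,
        "kept_paths": 91,
        "minimal_vertices": 39,
        "minimal_edges": 104,
        "hb_percentile": 33.0,
    },
)


FIXTURES = {
    f.name: f for f in (HALOGEN_EXCHANGE, CLAISEN, HYDROFORMYLATION)
}


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
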