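from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from reactnet import AtomList
from reactnet.fixtures import HALOGEN_EXCHANGE


def matrix_from_bonds(n: int, bonds) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in bonds:
        a[i, j] = a[j, i] = 1
    return a


@pytest.fixture
def halogen():
    """The six-atom 2 ICl + H2 worked system."""
    return HALOGEN_EXCHANGE


@pytest.fixture
def halogen_atoms():
    return HALOGEN_EXCHANGE.atom_list()


@pytest.fixture
def halogen_r(halogen):
    return halogen.reactant_matrix()


@pytest.fixture
def halogen_p(halogen):
    return halogen.product_matrix()


def atoms_of(symbols, active=None, catalyst=None) -> AtomList:
    return AtomList.from_symbols(symbols, active=active, catalyst=catalyst)
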