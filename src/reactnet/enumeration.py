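"""Breadth-first combinatorial generation of reaction intermediates.

Starting from the reactant AC matrix, conversion matrices are applied cycle
by cycle; every distinct matrix is visited once, permutational isomers are
collapsed to a single species via the canonical key, and states failing the
plausibility screens are discarded (and not extended).  The loop stops at
the fixed point — no new matrix generated — or after ``max_cycles``.

When the atom list flags a proper subset of atoms active (and
``cfg.active_mode`` is on), enumeration runs on the active-atom sub-matrix;
bonds touching inactive atoms are frozen and re-inserted from the reactant
template when states are expanded back to the all-atom basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .acmatrix import (
    CanonicalKey,
    CanonicalKeyer,
    component_labels,
    decompose_components,
    expand_active,
    project_active,
    require_valid,
)
from .atoms import AtomList
from .conversions import EnumerationConfig, enumerate_conversions


@dataclass
class SpeciesState:
    """One vertex of the chemical space: a full-system AC matrix.

    ``cycle`` records the conversion cycle at which the state was first
    reached; ``energy`` is filled only after an evaluator ran; ``smiles``
    holds one string per molecule once perception succeeded.
    """

    matrix: np.ndarray
    atoms: AtomList
    key: CanonicalKey
    cycle: int
    energy: float | None = None
    smiles: list[str] | None = None

    def components(self):
        return decompose_components(self.matrix)

    def __hash__(self):
        return hash(self.key)

    def __eq__(self, other):
        return isinstance(other, SpeciesState) and self.key == other.key


@dataclass
class EnumerationResult:
    """States found by :func:`enumerate_intermediates`, in discovery order."""

    states: dict[CanonicalKey, SpeciesState]
    cycle_counts: list[int]            # new species per cycle (index 0: the reactant)
    n_matrices_visited: int
    keyer: CanonicalKeyer

    @property
    def reactant_key(self) -> CanonicalKey:
        return next(iter(self.states))

    def ordered(self) -> list[SpeciesState]:
        return list(self.states.values())


def enumerate_intermediates(
    reactant_matrix: np.ndarray,
    atoms: AtomList,
    cfg: EnumerationConfig,
    screens: Callable[[np.ndarray], bool] | None = None,
    extra_screen: Callable[[np.ndarray], bool] | None = None,
) -> EnumerationResult:
    """Run the conversion cycles to the fixed point.

    ``screens`` receives the all-atom matrix of a candidate state and
    returns acceptance (typically :class:`reactnet.perception.StateScreens`);
    rejected states are dropped and never extended.  ``extra_screen`` hooks
    the optional in-flight ellipse criterion.  The result is empty iff the
    reactant itself fails the screens.
    """
    r_full = require_valid(reactant_matrix)
    keyer = CanonicalKeyer(atoms)

    active = cfg.active_mode and 0 < len(atoms.active_indices) < len(atoms)
    active_idx = np.asarray(atoms.active_indices, dtype=int)
    r_basis = project_active(r_full, atoms) if active else r_full

    def expand(basis: np.ndarray) -> np.ndarray:
        return expand_active(basis, r_full, atoms) if active else basis

    def accepts(full: np.ndarray) -> bool:
        if screens is not None and not screens(full):
            return False
        if extra_screen is not None and not extra_screen(full):
            return False
        return True

    result = EnumerationResult({}, [], 0, keyer)

    r_key = keyer.key(r_full)
    if not accepts(r_full):
        return result
    result.states[r_key] = SpeciesState(r_full, atoms, r_key, cycle=0)
    result.cycle_counts.append(1)

    degree_caps = None
    if screens is not None and hasattr(screens, "max_degrees"):
        degree_caps = np.asarray(screens.max_degrees(), dtype=int)
        if active:
            degree_caps = degree_caps[active_idx]

    seen = {r_basis.tobytes()}
    frontier = [r_basis]
    result.n_matrices_visited = 1
    cycle = 0
    while frontier and (cfg.max_cycles is None or cycle < cfg.max_cycles):
        cycle += 1
        new_frontier: list[np.ndarray] = []
        new_species = 0
        for basis in frontier:
            full = expand(basis)
            labels = component_labels(full)
            basis_labels = labels[active_idx] if active else labels
            spare = None
            if degree_caps is not None:
                degrees = np.asarray(full, dtype=int).sum(axis=0)
                spare = degree_caps - (degrees[active_idx] if active else degrees)
            for c in enumerate_conversions(basis, r_basis, cfg, basis_labels, spare):
                j_basis = (basis + c).astype(np.int8)
                b = j_basis.tobytes()
                if b in seen:
                    continue
                seen.add(b)
                result.n_matrices_visited += 1
                j_full = expand(j_basis)
                if not accepts(j_full):
                    continue
                key = keyer.key(j_full)
                if key not in result.states:
                    result.states[key] = SpeciesState(j_full, atoms, key, cycle)
                    new_species += 1
                new_frontier.append(j_basis)
        result.cycle_counts.append(new_species)
        frontier = new_frontier
    return result
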