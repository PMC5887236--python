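"""Conversion-matrix enumeration: one elementary bond-change step.

A conversion matrix C is symmetric with zero diagonal and entries in
{-1, 0, 1}; adding it to a state's AC matrix breaks (-1) and forms (+1)
bonds.  The admissible entries depend on both the current state I and the
original reactant matrix R:

* ``I_ij = 0, R_ij = 0``: the pair may stay apart or form a bond (C in {0, 1});
* ``I_ij = 0, R_ij = 1``: a reactant bond already broken in a previous cycle
  must not re-form (C = 0), which prevents regenerating earlier states;
* ``I_ij = 1, R_ij = 1``: a surviving reactant bond may break (C in {-1, 0});
* ``I_ij = 1, R_ij = 0``: a newly made bond is kept (C = 0), the mirror of
  the re-break rule.

Two global constraints apply per step: at most ``max_form`` formations and
``max_break`` dissociations, and the changed bonds may touch atoms from at
most ``molecularity`` connected components of the current state (uni- or
bimolecular steps only, by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np

from .acmatrix import component_labels


@dataclass
class EnumerationConfig:
    """Knobs of the combinatorial intermediate generation.

    max_form, max_break
        caps on bond formations / dissociations per elementary step
        (default 2 and 2).
    molecularity
        maximum number of reacting molecules per step; 1 or 2.
    max_cycles
        optional cap on conversion cycles (None: run to the fixed point).
    active_mode
        enumerate on the active-atom sub-matrix when the atom list flags a
        proper subset of atoms active.
    inflight_ellipse
        apply the ellipse (digression) criterion during enumeration rather
        than only afterwards.
    ring_bounds
        inclusive (min, max) per-molecule ring count admitted by the
        perception screen; ``max=None`` leaves rings unbounded.
    e_tol
        energy tolerance in kcal/mol for the post-enumeration screen.
    delta
        digression factor (bond changes) for the ellipse criterion.
    """

    max_form: int = 2
    max_break: int = 2
    molecularity: int = 2
    max_cycles: int | None = None
    active_mode: bool = True
    inflight_ellipse: bool = False
    ring_bounds: tuple[int, int | None] = (0, 0)
    e_tol: float = 20.0
    delta: int = 6

    def __post_init__(self):
        if self.max_form < 0 or self.max_break < 0:
            raise ValueError("bond-change caps must be >= 0")
        if self.molecularity not in (1, 2):
            raise ValueError("molecularity cap must be 1 or 2")
        if self.max_cycles is not None and self.max_cycles < 0:
            raise ValueError("max_cycles must be >= 0")


def changed_pairs(c: np.ndarray) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(formed, broken) bond pairs (i < j) of a conversion matrix."""
    tri = np.triu(np.asarray(c), k=1)
    formed = [tuple(map(int, ij)) for ij in np.argwhere(tri == 1)]
    broken = [tuple(map(int, ij)) for ij in np.argwhere(tri == -1)]
    return formed, broken


def apply_conversion(i_mat: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Apply one elementary step: ``I + C``.

    Raises if bases mismatch or the sum leaves {0, 1} (an illegal C).
    """
    i_mat = np.asarray(i_mat)
    c = np.asarray(c)
    if i_mat.shape != c.shape:
        raise ValueError(f"basis mismatch: {i_mat.shape} vs {c.shape}")
    out = i_mat + c
    if not np.isin(out, (0, 1)).all():
        raise ValueError("conversion produces entries outside {0,1}; illegal conversion matrix")
    return out.astype(np.int8)


def enumerate_conversions(
    i_mat: np.ndarray,
    r_mat: np.ndarray,
    cfg: EnumerationConfig,
    labels: Sequence[int] | None = None,
    spare: Sequence[int] | None = None,
) -> Iterator[np.ndarray]:
    """Yield every admissible nonzero conversion matrix for state ``i_mat``.

    ``labels`` assigns each basis atom its molecule label for the
    molecularity constraint; by default it is computed from ``i_mat``
    itself.  Active-atom enumeration passes labels derived from the
    expanded all-atom state so that "molecule" means the real molecule,
    not a fragment of the active sub-matrix.

    ``spare`` optionally gives each basis atom's remaining bonding capacity
    in the current state (maximum valence minus degree); formations that
    would exceed it are skipped.  Such states have no feasible bond-order
    assignment and would be discarded by the valence screen anyway, so the
    pruning only saves work.
    """
    i_mat = np.asarray(i_mat)
    r_mat = np.asarray(r_mat)
    if i_mat.shape != r_mat.shape:
        raise ValueError(f"basis mismatch: {i_mat.shape} vs {r_mat.shape}")
    n = i_mat.shape[0]
    if labels is None:
        labels = component_labels(i_mat)

    breakable = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if i_mat[i, j] == 1 and r_mat[i, j] == 1
    ]
    # an atom's capacity can grow by bonds broken in the same step, so the
    # prefilter allows for the maximum concurrent breaking at that atom
    headroom = None
    if spare is not None:
        breaks_possible = [0] * n
        for i, j in breakable:
            breaks_possible[i] += 1
            breaks_possible[j] += 1
        headroom = [
            spare[i] + min(cfg.max_break, breaks_possible[i]) for i in range(n)
        ]
    formable = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if i_mat[i, j] == 0 and r_mat[i, j] == 0
        and (headroom is None or (headroom[i] > 0 and headroom[j] > 0))
    ]

    for nb in range(min(cfg.max_break, len(breakable)) + 1):
        for brk in combinations(breakable, nb):
            breaks_at: dict[int, int] = {}
            for i, j in brk:
                breaks_at[i] = breaks_at.get(i, 0) + 1
                breaks_at[j] = breaks_at.get(j, 0) + 1
            for nf in range(min(cfg.max_form, len(formable)) + 1):
                if nf == 0 and nb == 0:
                    continue
                for form in combinations(formable, nf):
                    if spare is not None and nf > 0:
                        load: dict[int, int] = {}
                        for i, j in form:
                            load[i] = load.get(i, 0) + 1
                            load[j] = load.get(j, 0) + 1
                        if any(
                            cnt > spare[i] + breaks_at.get(i, 0)
                            for i, cnt in load.items()
                        ):
                            continue
                    touched = {labels[i] for ij in form + brk for i in ij}
                    if len(touched) > cfg.molecularity:
                        continue
                    c = np.zeros((n, n), dtype=np.int8)
                    for i, j in form:
                        c[i, j] = c[j, i] = 1
                    for i, j in brk:
                        c[i, j] = c[j, i] = -1
                    yield c
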