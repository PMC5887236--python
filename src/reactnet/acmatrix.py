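"""AC-matrix primitives: validation, block decomposition, canonical keys,
and the active-atom basis projection.

An AC matrix is a symmetric binary adjacency matrix over an ordered atom
list; a state containing several molecules is block-diagonalizable, and
:func:`decompose_components` recovers the blocks.  Permutational isomers
(element-preserving relabelings) are detected with the eigenvalue spectrum
of a modified Coulomb matrix, backed by an exact isomorphism check on
spectrum collisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .atoms import AtomList

#: spectrum entries are rounded to this many decimals before keying
SPECTRUM_DECIMALS = 6


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_ac`; ``ok`` iff all three checks pass."""

    symmetric: bool
    zero_diagonal: bool
    binary: bool
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.symmetric and self.zero_diagonal and self.binary


def validate_ac(a: np.ndarray) -> ValidationReport:
    """Check the AC-matrix invariants (symmetry, zero diagonal, 0/1 entries)."""
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"AC matrix must be square, got shape {a.shape}")
    problems = []
    symmetric = bool(np.array_equal(a, a.T))
    if not symmetric:
        ij = np.argwhere(a != a.T)
        problems.append(f"symmetry violated at {[tuple(map(int, x)) for x in ij[:5]]}")
    zero_diag = bool(np.all(np.diag(a) == 0))
    if not zero_diag:
        problems.append("nonzero diagonal entries")
    binary = bool(np.isin(a, (0, 1)).all())
    if not binary:
        problems.append("entries outside {0, 1}")
    return ValidationReport(symmetric, zero_diag, binary, problems)


def require_valid(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.int8)
    report = validate_ac(a)
    if not report.ok:
        raise ValueError("invalid AC matrix: " + "; ".join(report.problems))
    return a


def _union_find_labels(a: np.ndarray) -> list[int]:
    # tiny union-find; faster than sparse csgraph at molecule sizes
    n = a.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ii, jj = np.nonzero(np.triu(a, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots: dict[int, int] = {}
    labels = [0] * n
    for x in range(n):
        r = find(x)
        labels[x] = roots.setdefault(r, len(roots))
    return labels


def decompose_components(a: np.ndarray) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Connected components of the bond graph.

    Returns one ``(atom indices, induced sub-matrix)`` pair per molecule;
    the index sets partition the atom list.
    """
    a = np.asarray(a)
    labels = _union_find_labels(a)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    out = []
    for lab in sorted(groups):
        idx = tuple(groups[lab])
        out.append((idx, a[np.ix_(idx, idx)]))
    return out


def component_labels(a: np.ndarray) -> np.ndarray:
    """Per-atom molecule label (used by the molecularity constraint)."""
    return np.asarray(_union_find_labels(np.asarray(a)))


def alt_coulomb_matrix(a: np.ndarray, atoms: AtomList) -> np.ndarray:
    """Coulomb-like matrix modified for graph-isomorphism detection.

    Diagonal ``0.5 * Z_i**2.4`` identifies the element; off-diagonal
    ``A_ij * Z_i * Z_j`` encodes connectivity weighted by the bonded
    elements, so the eigenvalue spectrum is invariant under any
    element-preserving permutation.
    """
    z = atoms.z
    m = np.asarray(a, dtype=float) * np.outer(z, z)
    np.fill_diagonal(m, 0.5 * z ** 2.4)
    return m


def spectrum_key(a: np.ndarray, atoms: AtomList) -> tuple[float, ...]:
    """Sorted, rounded eigenvalue spectrum of the alternative Coulomb matrix."""
    eig = np.linalg.eigvalsh(alt_coulomb_matrix(a, atoms))
    rounded = np.round(eig, SPECTRUM_DECIMALS)
    rounded[rounded == 0.0] = 0.0  # canonicalize -0.0
    return tuple(float(v) for v in rounded)


def _as_labeled_graph(a: np.ndarray, atoms: AtomList) -> nx.Graph:
    g = nx.Graph()
    for i, atom in enumerate(atoms):
        g.add_node(i, element=atom.symbol)
    ii, jj = np.nonzero(np.triu(np.asarray(a), k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def states_isomorphic(a: np.ndarray, b: np.ndarray, atoms: AtomList) -> bool:
    """Exact element-preserving graph isomorphism (VF2)."""
    ga = _as_labeled_graph(a, atoms)
    gb = _as_labeled_graph(b, atoms)
    nm = nx.algorithms.isomorphism.categorical_node_match("element", None)
    return nx.is_isomorphic(ga, gb, node_match=nm)


def canonical_key(a: np.ndarray, atoms: AtomList) -> tuple[float, ...]:
    """Permutation-invariant key of a state (its rounded spectrum).

    Equal for permutationally isomorphic states.  Distinct non-isomorphic
    states are almost always separated by the spectrum; the rare cospectral
    collisions are resolved by :class:`CanonicalKeyer`, which confirms every
    collision with an exact isomorphism check.
    """
    return spectrum_key(a, atoms)


@dataclass(frozen=True)
class CanonicalKey:
    """Final state identity: spectrum plus a collision ordinal."""

    spectrum: tuple[float, ...]
    ordinal: int = 0

    def __lt__(self, other: "CanonicalKey") -> bool:
        return (self.spectrum, self.ordinal) < (other.spectrum, other.ordinal)

    def short(self) -> str:
        return f"{hash(self.spectrum) & 0xFFFFFFFF:08x}.{self.ordinal}"


def _neighborhood_invariant(a: np.ndarray, atoms: AtomList) -> tuple:
    """Permutation-invariant refinement: sorted (element, neighbor elements)."""
    symbols = atoms.symbols
    ii, jj = np.nonzero(a)
    neigh: list[list[str]] = [[] for _ in range(len(atoms))]
    for i, j in zip(ii.tolist(), jj.tolist()):
        neigh[i].append(symbols[j])
    return tuple(sorted((symbols[i], tuple(sorted(ns))) for i, ns in enumerate(neigh)))


class CanonicalKeyer:
    """Assigns collision-free canonical keys within one run.

    States are bucketed by (spectrum, neighborhood invariant); cospectral
    but non-isomorphic states receive distinct ordinals through an exact
    isomorphism check that runs only on bucket collisions.
    """

    #: brute-force canonicalization is used when the total number of
    #: within-element permutations stays below this
    MAX_EXACT_PERMS = 10_000

    def __init__(self, atoms: AtomList):
        self.atoms = atoms
        self._buckets: dict[tuple, list[tuple[np.ndarray, int]]] = {}
        self._per_spectrum: dict[tuple, int] = {}
        self._perms = self._all_class_permutations()
        self._canon_cache: dict[bytes, CanonicalKey] = {}
        self._canon_keys: dict[bytes, CanonicalKey] = {}

    def _all_class_permutations(self):
        from itertools import permutations as iperm
        from itertools import product as iprod
        from math import factorial, prod

        classes = list(self.atoms.element_classes().values())
        if prod(factorial(len(c)) for c in classes) > self.MAX_EXACT_PERMS:
            return None
        perms = []
        for combo in iprod(*(iperm(c) for c in classes)):
            p = np.empty(len(self.atoms), dtype=int)
            for ix, perm in zip(classes, combo):
                p[list(ix)] = perm
            perms.append(p)
        return perms

    def key(self, a: np.ndarray) -> CanonicalKey:
        a = np.asarray(a, dtype=np.int8)
        if self._perms is not None:
            cached = self._canon_cache.get(a.tobytes())
            if cached is not None:
                return cached
            canon = min(a[np.ix_(p, p)].tobytes() for p in self._perms)
            key = self._canon_keys.get(canon)
            if key is None:
                spec = spectrum_key(a, self.atoms)
                ordinal = self._per_spectrum.get(spec, 0)
                self._per_spectrum[spec] = ordinal + 1
                key = CanonicalKey(spec, ordinal)
                self._canon_keys[canon] = key
            self._canon_cache[a.tobytes()] = key
            return key
        spec = spectrum_key(a, self.atoms)
        bucket_id = (spec, _neighborhood_invariant(a, self.atoms))
        reps = self._buckets.setdefault(bucket_id, [])
        for rep, ordinal in reps:
            if np.array_equal(rep, a) or states_isomorphic(rep, a, self.atoms):
                return CanonicalKey(spec, ordinal)
        # ordinal unique per spectrum (across refinement buckets)
        ordinal = self._per_spectrum.get(spec, 0)
        self._per_spectrum[spec] = ordinal + 1
        reps.append((np.asarray(a, dtype=np.int8).copy(), ordinal))
        return CanonicalKey(spec, ordinal)


def project_active(a_all: np.ndarray, atoms: AtomList) -> np.ndarray:
    """Restrict an all-atom AC matrix to the active-atom basis."""
    idx = atoms.active_indices
    if not idx:
        raise ValueError("active-atom projection requires at least one active atom")
    return np.asarray(a_all)[np.ix_(idx, idx)].copy()


def expand_active(a_active: np.ndarray, template_all: np.ndarray, atoms: AtomList) -> np.ndarray:
    """Re-insert untouched bonds around an active-basis matrix.

    Bonds involving at least one inactive atom are copied from the template
    (they never change during active-atom enumeration); the active-active
    block is replaced by ``a_active``.
    """
    idx = atoms.active_indices
    if not idx:
        raise ValueError("active-atom expansion requires at least one active atom")
    a_active = np.asarray(a_active)
    if a_active.shape != (len(idx), len(idx)):
        raise ValueError(
            f"active matrix shape {a_active.shape} does not match {len(idx)} active atoms"
        )
    full = np.asarray(template_all, dtype=np.int8).copy()
    full[np.ix_(idx, idx)] = a_active
    return full
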