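"""Chemical distance (CD) between states.

CD(A, B) is the number of bond changes converting one state into the other:
half the entrywise |A - B| for a fixed atom order, and, because like atoms
are interchangeable, the reported distance is the minimum over all
element-preserving permutations.  The minimization is solved as a
mixed-integer linear program: binary assignment variables p_uv map atom u of
A onto like-element atom v of B under doubly stochastic constraints, and the
number of preserved bonds is maximized through linearized edge-match
variables, giving CD = |E_A| + |E_B| - 2 * (matched bonds).

The MILP runs through scipy's HiGHS backend with a per-pair time limit;
when the solver returns no proven optimum the best feasible mapping found
(or the in-class identity mapping) is used and flagged in the result status.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import csr_matrix

from .atoms import AtomList


@dataclass
class DistanceResult:
    """Minimized CD with the optimal atom mapping (A index -> B index)."""

    value: int
    mapping: tuple[int, ...]
    status: str = "optimal"


def cd_fixed(a: np.ndarray, b: np.ndarray) -> int:
    """Bond changes under the given atom order: 0.5 * sum |A - B|."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"basis mismatch: {a.shape} vs {b.shape}")
    return int(np.abs(a - b).sum() // 2)


def _edges(a: np.ndarray) -> list[tuple[int, int]]:
    ii, jj = np.nonzero(np.triu(np.asarray(a), k=1))
    return list(zip(ii.tolist(), jj.tolist()))


def _edge_type(e: tuple[int, int], symbols: Sequence[str]) -> tuple[str, str]:
    s = sorted((symbols[e[0]], symbols[e[1]]))
    return (s[0], s[1])


def _mapping_value(a: np.ndarray, b: np.ndarray, perm: Sequence[int]) -> int:
    perm = np.asarray(perm)
    b_mapped = b[np.ix_(perm, perm)]
    # b_mapped[i][j] = B[perm[i]][perm[j]]: B pulled back onto A's index space
    return cd_fixed(a, b_mapped)


def _class_identity_mapping(atoms_a: AtomList, atoms_b: AtomList) -> list[int]:
    """Map each element class of A onto B's class in index order."""
    mapping = [-1] * len(atoms_a)
    classes_b = {sym: list(ix) for sym, ix in atoms_b.element_classes().items()}
    for u, atom in enumerate(atoms_a):
        mapping[u] = classes_b[atom.symbol].pop(0)
    return mapping


def cd_min(
    a: np.ndarray,
    b: np.ndarray,
    atoms_a: AtomList,
    atoms_b: AtomList | None = None,
    time_limit: float = 10.0,
) -> DistanceResult:
    """Minimum CD over element-preserving atom permutations.

    ``atoms_b`` defaults to ``atoms_a`` (states on a shared basis).  States
    with different element multisets are not interconvertible and raise.
    """
    atoms_b = atoms_b or atoms_a
    a = np.asarray(a)
    b = np.asarray(b)
    if Counter(atoms_a.symbols) != Counter(atoms_b.symbols):
        raise ValueError("element multisets differ; states are not interconvertible")
    if a.shape[0] != len(atoms_a) or b.shape[0] != len(atoms_b):
        raise ValueError("matrix dimension does not match atom list")

    symbols_a, symbols_b = atoms_a.symbols, atoms_b.symbols
    edges_a, edges_b = _edges(a), _edges(b)
    types_a = Counter(_edge_type(e, symbols_a) for e in edges_a)
    types_b = Counter(_edge_type(f, symbols_b) for f in edges_b)
    common_cap = sum(min(types_a[t], types_b[t]) for t in types_a)
    lower_bound = len(edges_a) + len(edges_b) - 2 * common_cap

    # cheap exits: a mapping achieving the type-count bound is optimal
    if atoms_a is atoms_b or symbols_a == symbols_b:
        identity = list(range(len(atoms_a)))
        v = cd_fixed(a, b)
        if v == lower_bound:
            return DistanceResult(v, tuple(identity))
    start = _class_identity_mapping(atoms_a, atoms_b)
    v = _mapping_value(a, b, start)
    if v == lower_bound:
        return DistanceResult(v, tuple(start))

    mapping, status = _solve_milp(
        a, b, symbols_a, symbols_b, edges_a, edges_b, time_limit
    )
    if mapping is None:
        warnings.warn("chemical-distance MILP returned no mapping; using in-class identity")
        return DistanceResult(v, tuple(start), status="fallback")
    value = _mapping_value(a, b, mapping)
    if value > v:  # solver stopped early with a worse incumbent
        return DistanceResult(v, tuple(start), status="fallback")
    return DistanceResult(value, tuple(mapping), status=status)


def _solve_milp(a, b, symbols_a, symbols_b, edges_a, edges_b, time_limit):
    n = len(symbols_a)
    allowed: dict[tuple[int, int], int] = {}
    for u in range(n):
        for v in range(n):
            if symbols_a[u] == symbols_b[v]:
                allowed[(u, v)] = len(allowed)
    nx_vars = len(allowed)

    pairs = []
    for e in edges_a:
        te = _edge_type(e, symbols_a)
        for f in edges_b:
            if te == _edge_type(f, symbols_b):
                pairs.append((e, f))
    ny = len(pairs)
    nvar = nx_vars + ny

    rows, cols, vals = [], [], []
    lb, ub = [], []
    row = 0
    for u in range(n):  # each A atom maps somewhere
        for v in range(n):
            k = allowed.get((u, v))
            if k is not None:
                rows.append(row)
                cols.append(k)
                vals.append(1.0)
        lb.append(1.0)
        ub.append(1.0)
        row += 1
    for v in range(n):  # each B atom is hit once
        for u in range(n):
            k = allowed.get((u, v))
            if k is not None:
                rows.append(row)
                cols.append(k)
                vals.append(1.0)
        lb.append(1.0)
        ub.append(1.0)
        row += 1
    for idx, ((i, j), (u, v)) in enumerate(pairs):
        yk = nx_vars + idx
        for anchor in (i, j):
            rows.append(row)
            cols.append(yk)
            vals.append(1.0)
            for target in (u, v):
                k = allowed.get((anchor, target))
                if k is not None:
                    rows.append(row)
                    cols.append(k)
                    vals.append(-1.0)
            lb.append(-np.inf)
            ub.append(0.0)
            row += 1

    c = np.zeros(nvar)
    c[nx_vars:] = -1.0  # maximize matched bonds
    integrality = np.zeros(nvar)
    integrality[:nx_vars] = 1
    constraints = LinearConstraint(
        csr_matrix((vals, (rows, cols)), shape=(row, nvar)), lb, ub
    )
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=(0, 1),
        options={"time_limit": time_limit, "presolve": True},
    )
    if res.x is None:
        return None, "infeasible"
    mapping = [-1] * n
    for (u, v), k in allowed.items():
        if res.x[k] > 0.5:
            mapping[u] = v
    if -1 in mapping:
        return None, "incomplete"
    status = "optimal" if res.status == 0 else "time_limit"
    return mapping, status


class CDCache:
    """Memoized chemical distances between species states.

    Distances are keyed by the unordered pair of canonical keys (CD is
    symmetric).  ``basis`` selects whether distances are evaluated on the
    all-atom matrices (default) or on the active-atom sub-matrices.
    """

    def __init__(
        self,
        atoms: AtomList,
        basis: str = "all",
        time_limit: float = 10.0,
    ):
        if basis not in ("all", "active"):
            raise ValueError("basis must be 'all' or 'active'")
        self.atoms = atoms
        self.basis = basis
        self.time_limit = time_limit
        self._memo: dict = {}
        self._info: dict = {}
        if basis == "active":
            self._active_idx = atoms.active_indices
            self._active_atoms = atoms.subset(self._active_idx)

    def _matrix(self, state) -> np.ndarray:
        if self.basis == "active":
            return np.asarray(state.matrix)[np.ix_(self._active_idx, self._active_idx)]
        return state.matrix

    def _state_info(self, state):
        """Cached (matrix, edge count, edge-type Counter) per state."""
        info = self._info.get(state.key)
        if info is None:
            m = self._matrix(state)
            symbols = self._atoms_for_basis().symbols
            edges = _edges(m)
            info = (m, len(edges), Counter(_edge_type(e, symbols) for e in edges))
            self._info[state.key] = info
        return info

    def lower_bound(self, u, v) -> int:
        """Edge-type-count lower bound on the minimized CD (cheap)."""
        if u.key == v.key:
            return 0
        mu, eu, tu = self._state_info(u)
        mv, ev, tv = self._state_info(v)
        common = sum(min(n, tv[t]) for t, n in tu.items())
        return eu + ev - 2 * common

    def distance(self, u, v) -> DistanceResult:
        if u.key == v.key:
            return DistanceResult(0, tuple(range(len(self._atoms_for_basis()))))
        pair = (u.key, v.key) if u.key < v.key else (v.key, u.key)
        res = self._memo.get(pair)
        if res is None:
            a, b = (u, v) if u.key < v.key else (v, u)
            ma, ea, ta = self._state_info(a)
            mb, eb, tb = self._state_info(b)
            common = sum(min(n, tb[t]) for t, n in ta.items())
            bound = ea + eb - 2 * common
            fixed = cd_fixed(ma, mb)
            if fixed == bound:  # identity mapping is provably optimal
                res = DistanceResult(fixed, tuple(range(ma.shape[0])))
            else:
                res = cd_min(
                    ma, mb, self._atoms_for_basis(), time_limit=self.time_limit
                )
            self._memo[pair] = res
        if u.key < v.key:
            return res
        return self._reversed(res)

    def _reversed(self, res: DistanceResult) -> DistanceResult:
        inv = [0] * len(res.mapping)
        for i, m in enumerate(res.mapping):
            inv[m] = i
        return DistanceResult(res.value, tuple(inv), res.status)

    def __call__(self, u, v) -> int:
        return self.distance(u, v).value

    def _atoms_for_basis(self) -> AtomList:
        return self._active_atoms if self.basis == "active" else self.atoms


def ellipse_filter(
    states: Iterable,
    r_state,
    p_state,
    delta: int,
    cd: Callable,
) -> list:
    """Keep states inside the ellipse CD(R,I) + CD(I,P) <= CD(R,P) + delta.

    R and P are the foci and always survive (their sums equal CD(R,P)).
    ``cd`` is a callable returning the minimized chemical distance between
    two states, e.g. a :class:`CDCache`.
    """
    if delta < 0:
        raise ValueError("digression factor must be >= 0")
    threshold = cd(r_state, p_state) + delta
    kept = []
    for s in states:
        if s.key in (r_state.key, p_state.key):
            kept.append(s)
            continue
        if cd(r_state, s) + cd(s, p_state) <= threshold:
            kept.append(s)
    return kept
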