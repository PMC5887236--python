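"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written the slow, obvious way and shares no
code path with the package internals it checks.
"""

from __future__ import annotations

from itertools import combinations, permutations, product

import networkx as nx
import numpy as np


def _pairs(n):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def components_slow(a: np.ndarray) -> list[set[int]]:
    g = nx.from_numpy_array(np.asarray(a, dtype=float))
    return [set(c) for c in nx.connected_components(g)]


def brute_force_conversions(
    i_mat: np.ndarray,
    r_mat: np.ndarray,
    max_form: int = 2,
    max_break: int = 2,
    molecularity: int = 2,
) -> set[bytes]:
    """All admissible conversion matrices, enumerated exhaustively.

    Iterates over every symmetric zero-diagonal {-1,0,1} matrix with at
    most ``max_form + max_break`` nonzero bond pairs (larger matrices are
    excluded by the caps) and keeps those obeying the elementwise rules,
    the caps, and the molecularity constraint.  Returned as a set of
    matrix byte representations.
    """
    i_mat = np.asarray(i_mat)
    r_mat = np.asarray(r_mat)
    n = i_mat.shape[0]
    comps = components_slow(i_mat)
    comp_of = {}
    for ci, members in enumerate(comps):
        for m in members:
            comp_of[m] = ci
    out = set()
    pair_list = _pairs(n)
    for k in range(1, max_form + max_break + 1):
        for chosen in combinations(pair_list, k):
            for signs in product((-1, 1), repeat=k):
                c = np.zeros((n, n), dtype=np.int8)
                for (i, j), s in zip(chosen, signs):
                    c[i, j] = c[j, i] = s
                if _conversion_ok(c, i_mat, r_mat, max_form, max_break, molecularity, comp_of):
                    out.add(c.tobytes())
    return out


def _conversion_ok(c, i_mat, r_mat, max_form, max_break, molecularity, comp_of):
    n = c.shape[0]
    n_form = n_break = 0
    touched = set()
    for i in range(n):
        for j in range(i + 1, n):
            v = c[i, j]
            if v == 0:
                continue
            if i_mat[i, j] == 0:
                if v != 1 or r_mat[i, j] == 1:
                    return False
                n_form += 1
            else:
                if v != -1 or r_mat[i, j] == 0:
                    return False
                n_break += 1
            touched.add(comp_of[i])
            touched.add(comp_of[j])
    if n_form > max_form or n_break > max_break:
        return False
    if len(touched) > molecularity:
        return False
    return True


def graphs_isomorphic(a, b, symbols) -> bool:
    ga = nx.from_numpy_array(np.asarray(a, dtype=float))
    gb = nx.from_numpy_array(np.asarray(b, dtype=float))
    for g in (ga, gb):
        for i in g.nodes:
            g.nodes[i]["element"] = symbols[i]
    return nx.is_isomorphic(
        ga, gb, node_match=nx.algorithms.isomorphism.categorical_node_match("element", None)
    )


def brute_force_reachable(
    r_mat: np.ndarray,
    symbols,
    screen=None,
    max_form: int = 2,
    max_break: int = 2,
    molecularity: int = 2,
) -> list[np.ndarray]:
    """Exhaustive state reachability from the reactant.

    Breadth-first over exact matrices using the exhaustive conversion
    oracle; states failing ``screen`` are dropped and not extended.  The
    result collapses permutational isomers: one representative per
    element-preserving isomorphism class, in discovery order.
    """
    r_mat = np.asarray(r_mat, dtype=np.int8)
    if screen is not None and not screen(r_mat):
        return []
    seen = {r_mat.tobytes()}
    frontier = [r_mat]
    accepted = [r_mat]
    while frontier:
        nxt = []
        for state in frontier:
            for cb in sorted(brute_force_conversions(state, r_mat, max_form, max_break, molecularity)):
                c = np.frombuffer(cb, dtype=np.int8).reshape(state.shape)
                j = (state + c).astype(np.int8)
                if j.tobytes() in seen:
                    continue
                seen.add(j.tobytes())
                if screen is not None and not screen(j):
                    continue
                accepted.append(j)
                nxt.append(j)
        frontier = nxt
    classes: list[np.ndarray] = []
    for state in accepted:
        if not any(graphs_isomorphic(state, rep, symbols) for rep in classes):
            classes.append(state)
    return classes


def brute_force_cd(a: np.ndarray, b: np.ndarray, symbols) -> int:
    """Minimum CD by exhaustive permutation within element classes."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(symbols)
    classes: dict[str, list[int]] = {}
    for i, s in enumerate(symbols):
        classes.setdefault(s, []).append(i)
    class_lists = list(classes.values())
    best = None
    for perms in product(*(permutations(ix) for ix in class_lists)):
        mapping = [0] * n
        for ix, perm in zip(class_lists, perms):
            for src, dst in zip(ix, perm):
                mapping[src] = dst
        m = np.asarray(mapping)
        b_mapped = b[np.ix_(m, m)]
        v = int(np.abs(a - b_mapped).sum() // 2)
        if best is None or v < best:
            best = v
            if best == 0:
                break
    return best


def brute_force_paths_through(g: nx.Graph, r, p, v) -> list[tuple]:
    """All minimal-length simple R->P paths through v, by full enumeration."""
    best = None
    found = []
    for path in nx.all_simple_paths(g, r, p):
        if v not in path:
            continue
        length = sum(g.edges[x, y]["weight"] for x, y in zip(path, path[1:]))
        if best is None or length < best:
            best = length
            found = [tuple(path)]
        elif length == best:
            found.append(tuple(path))
    return sorted(found)
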