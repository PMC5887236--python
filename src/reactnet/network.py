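"""Reaction-network construction, shortest-path sampling, and graph filters.

Vertices are species states; an undirected edge is an admissible elementary
reaction: the CD-optimal atom mapping between the endpoints must change at
most ``max_form`` + ``max_break`` bonds respecting the individual caps, the
changed bonds may touch at most ``molecularity`` molecules of (at least)
one endpoint, and in catalytic runs at least one changed bond must touch a
catalyst atom.  Edge weights are the minimized chemical distances, so path
lengths count total bond changes — the principle of minimum structure
change makes short paths the kinetically plausible ones.

Path sampling follows the Dijkstra/Yen scheme: for every vertex v, all
equidistant shortest reactant->v->product loopless paths are collected;
the union over v defines the sampled paths, and the minimal subnetwork is
the R/P-containing component of the sampled-edge subgraph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import islice, product
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .acmatrix import CanonicalKey, component_labels
from .chemdist import CDCache
from .enumeration import SpeciesState

#: deterministic cap on tie enumeration / Yen scans per vertex
MAX_TIES_PER_VERTEX = 1000


@dataclass
class NetworkConfig:
    """Edge admissibility rules (mirrors the enumeration constraints)."""

    max_form: int = 2
    max_break: int = 2
    molecularity: int = 2
    require_catalyst: bool | None = None  # None: require iff catalyst atoms flagged


@dataclass
class ReactionPath:
    """Loopless reactant-to-product vertex sequence with its CD length."""

    keys: tuple[CanonicalKey, ...]
    length: float
    rank: int | None = None
    percentile: float | None = None

    def __iter__(self):
        return iter(self.keys)


def _changed_bonds(u: SpeciesState, v: SpeciesState, cd_cache: CDCache):
    """(formed, broken) bond index pairs in full-atom space, u -> v."""
    res = cd_cache.distance(u, v)
    perm = np.asarray(res.mapping)
    mu = cd_cache._matrix(u)
    mv = cd_cache._matrix(v)
    v_pulled = mv[np.ix_(perm, perm)]
    diff = v_pulled.astype(int) - mu.astype(int)
    if cd_cache.basis == "active":
        to_full = cd_cache._active_idx
    else:
        to_full = tuple(range(len(u.atoms)))
    formed = [
        (to_full[int(i)], to_full[int(j)]) for i, j in zip(*np.nonzero(np.triu(diff == 1, k=1)))
    ]
    broken = [
        (to_full[int(i)], to_full[int(j)]) for i, j in zip(*np.nonzero(np.triu(diff == -1, k=1)))
    ]
    return res, formed, broken


def build_network(
    states: Iterable[SpeciesState],
    r_key: CanonicalKey,
    p_key: CanonicalKey,
    cd_cache: CDCache,
    cfg: NetworkConfig | None = None,
) -> nx.Graph:
    """Connect admissible state pairs into the CD-weighted reaction network."""
    cfg = cfg or NetworkConfig()
    states = sorted(states, key=lambda s: s.key)
    by_key = {s.key: s for s in states}
    if r_key not in by_key or p_key not in by_key:
        raise ValueError("reactant and product states must be among the network vertices")

    g = nx.Graph(reactant=r_key, product=p_key)
    for s in states:
        g.add_node(s.key, state=s)

    atoms = states[0].atoms
    catalyst = set(atoms.catalyst_indices)
    require_cat = cfg.require_catalyst
    if require_cat is None:
        require_cat = bool(catalyst)

    for a_i in range(len(states)):
        u = states[a_i]
        labels_u = component_labels(u.matrix)
        cap_sum = cfg.max_form + cfg.max_break
        for b_i in range(a_i + 1, len(states)):
            v = states[b_i]
            if cd_cache.lower_bound(u, v) > cap_sum:
                continue  # no admissible mapping can satisfy the caps
            res, formed, broken = _changed_bonds(u, v, cd_cache)
            if res.value == 0:
                continue  # permutational isomers collapse to one vertex
            if len(formed) > cfg.max_form or len(broken) > cfg.max_break:
                continue
            changed = formed + broken
            touched_u = {labels_u[i] for ij in changed for i in ij}
            if len(touched_u) > cfg.molecularity:
                # the reverse reaction may still be uni/bimolecular:
                # translate changed bonds into v's index space via the mapping
                labels_v = component_labels(v.matrix)
                mapping = np.asarray(res.mapping)
                if cd_cache.basis == "active":
                    act = {g_idx: k for k, g_idx in enumerate(cd_cache._active_idx)}
                    touched_v = {
                        labels_v[cd_cache._active_idx[int(mapping[act[i]])]]
                        for ij in changed
                        for i in ij
                    }
                else:
                    touched_v = {labels_v[int(mapping[i])] for ij in changed for i in ij}
                if len(touched_v) > cfg.molecularity:
                    continue
            if require_cat and not any(
                i in catalyst or j in catalyst for i, j in changed
            ):
                continue
            g.add_edge(
                u.key,
                v.key,
                weight=int(res.value),
                formed=tuple(formed),
                broken=tuple(broken),
                catalyst_involved=any(i in catalyst or j in catalyst for i, j in changed),
            )
    return g


def _path_length(g: nx.Graph, keys: Sequence) -> float:
    return sum(g.edges[a, b]["weight"] for a, b in zip(keys, keys[1:]))


def shortest_paths_through(
    g: nx.Graph, v, k: int = 1, max_ties: int = MAX_TIES_PER_VERTEX
) -> list[ReactionPath]:
    """All minimal-length loopless R -> v -> P paths.

    Ties are enumerated by composing the shortest-path DAGs of the two
    legs; when every composition repeats a vertex, a Yen-style scan over
    loopless R->P paths finds the shortest ones passing through v.
    ``k > 1`` extends the sampling to the k shortest distinct path lengths
    through v.  Returns [] when v is disconnected from either endpoint.

    Degenerate networks (many equal-weight edges) can hold astronomically
    many equidistant geodesics; enumeration is truncated deterministically
    at ``max_ties`` paths per vertex, with a warning.
    """
    r, p = g.graph["reactant"], g.graph["product"]
    if v not in g:
        raise ValueError("vertex not in network")
    if k > 1:
        paths = _yen_paths_through(g, v, r, p, k=k, max_scan=max_ties)
        return [ReactionPath(keys, _path_length(g, keys)) for keys in sorted(set(paths))]
    dist_r = nx.single_source_dijkstra_path_length(g, r, weight="weight")
    dist_p = nx.single_source_dijkstra_path_length(g, p, weight="weight")
    if v not in dist_r or v not in dist_p:
        return []
    paths = _tie_paths(g, v, dist_r, dist_p, max_ties)
    if not paths:
        # every leg composition clashes: the minimal loopless length through
        # v exceeds dist(R,v) + dist(v,P).  A min-cost-flow (two internally
        # disjoint legs) gives the exact optimum; ties are then enumerated
        # by a bounded depth-first search.
        length = _min_length_through_flow(g, v, r, p)
        if length is None:
            return []
        paths = _exact_paths_through(g, v, r, p, length, dist_p, max_ties)
        if not paths:
            return []
    out = [ReactionPath(keys, _path_length(g, keys)) for keys in sorted(set(paths))]
    return out


def _min_length_through_flow(g, v, r, p):
    """Minimal total weight of a loopless r -> v -> p path.

    Solved as a min-cost flow on the node-split digraph: two units leave v,
    one must reach r and one p, and unit node capacities force the two legs
    to be internally vertex-disjoint.  Returns None when no such path
    exists.
    """
    if v in (r, p):
        try:
            return nx.dijkstra_path_length(g, r, p, weight="weight")
        except nx.NetworkXNoPath:
            return None
    d = nx.DiGraph()
    for x in g.nodes:
        if x in (v, r, p):
            continue
        d.add_edge((x, 0), (x, 1), capacity=1, weight=0)
    for x, y, w in g.edges(data="weight"):
        for a, b in ((x, y), (y, x)):
            if a in (r, p) or b == v:
                continue  # sinks have no outflow; the source is not re-entered
            src = (a, 1)
            dst = (b, 0)
            d.add_edge(src, dst, capacity=1, weight=int(w))
    for node, demand in (((v, 1), -2), ((r, 0), 1), ((p, 0), 1)):
        if node not in d:
            d.add_node(node)
        d.nodes[node]["demand"] = demand
    try:
        flow = nx.min_cost_flow(d)
    except nx.NetworkXUnfeasible:
        return None
    return nx.cost_of_flow(d, flow)


def _exact_paths_through(g, v, r, p, length, dist_p, max_ties):
    """All simple r->p paths through v of exactly the given total weight.

    Depth-first with admissible pruning (remaining distance bounds) and a
    deterministic work budget.
    """
    dist_v = nx.single_source_dijkstra_path_length(g, v, weight="weight")
    inf = float("inf")
    found: list[tuple] = []
    budget = [max(200 * max_ties, 10_000)]

    def dfs(x, acc, path, used, seen_v):
        if budget[0] <= 0 or len(found) >= max_ties:
            return
        budget[0] -= 1
        if x == p:
            if seen_v and acc == length:
                found.append(tuple(path))
            return
        for y in sorted(g.neighbors(x)):
            if y in used:
                continue
            w = g.edges[x, y]["weight"]
            hit_v = seen_v or y == v
            bound = dist_p.get(y, inf) if hit_v else dist_v.get(y, inf) + dist_v.get(p, inf)
            if acc + w + bound > length:
                continue
            used.add(y)
            path.append(y)
            dfs(y, acc + w, path, used, hit_v)
            path.pop()
            used.remove(y)

    dfs(r, 0, [r], {r}, v == r)
    if len(found) >= max_ties or budget[0] <= 0:
        warnings.warn(
            f"tie enumeration truncated at {max_ties} paths through one vertex; "
            "path counts are a deterministic sample, not the full tie set"
        )
    return found


def _tie_paths(g, v, dist_r, dist_p, max_ties) -> list[tuple]:
    """Loopless R->v->P compositions of the two shortest-path DAGs.

    Depth-first over geodesic edges with a visited-set check, so clashing
    compositions are pruned as they arise rather than generated and
    discarded.  Deterministically truncated at ``max_ties`` results (or a
    proportional work budget), with a warning.
    """
    r, p = g.graph["reactant"], g.graph["product"]
    if v not in dist_r or v not in dist_p:
        return []
    dist_v = nx.single_source_dijkstra_path_length(g, v, weight="weight")
    if r not in dist_v or p not in dist_v:
        return []
    found: list[tuple] = []
    budget = [max(200 * max_ties, 10_000)]
    truncated = [False]

    # geodesic successor lists, computed once: edges of the r->v leg
    # oriented toward v, and of the v->p leg oriented toward p
    inf = float("inf")
    succ1: dict = {}
    succ2: dict = {}
    target1 = dist_r[v]
    target2 = dist_v[p]
    for x, y, w in g.edges(data="weight"):
        for a, b in ((x, y), (y, x)):
            if dist_r.get(a, inf) + w + dist_v.get(b, inf) == target1:
                succ1.setdefault(a, []).append(b)
            if dist_v.get(a, inf) + w + dist_p.get(b, inf) == target2:
                succ2.setdefault(a, []).append(b)
    for adj in (succ1, succ2):
        for ys in adj.values():
            ys.sort()

    def dfs2(x, path, used):
        if budget[0] <= 0 or len(found) >= max_ties:
            truncated[0] = True
            return
        budget[0] -= 1
        if x == p:
            found.append(tuple(path))
            return
        for y in succ2.get(x, ()):
            if y in used:
                continue
            used.add(y)
            path.append(y)
            dfs2(y, path, used)
            path.pop()
            used.remove(y)

    def dfs1(x, path, used):
        if budget[0] <= 0 or len(found) >= max_ties:
            truncated[0] = True
            return
        budget[0] -= 1
        if x == v:
            dfs2(v, path, used)
            return
        for y in succ1.get(x, ()):
            if y in used:
                continue
            used.add(y)
            path.append(y)
            dfs1(y, path, used)
            path.pop()
            used.remove(y)

    dfs1(r, [r], {r})
    if truncated[0] or len(found) >= max_ties:
        warnings.warn(
            f"tie enumeration truncated at {max_ties} paths through one vertex; "
            "path counts are a deterministic sample, not the full tie set"
        )
    return found


def _yen_paths_through(g, v, r, p, k: int = 1, max_scan: int = MAX_TIES_PER_VERTEX) -> list[tuple]:
    """Shortest loopless R->P paths through v by scanning Yen's enumeration.

    Collects the paths belonging to the ``k`` smallest total lengths among
    loopless paths passing through v.
    """
    lengths_seen: list[float] = []
    found = []
    try:
        gen = nx.shortest_simple_paths(g, r, p, weight="weight")
    except nx.NetworkXNoPath:
        return []
    try:
        for path in islice(gen, max(500, max_scan * 5)):
            length = _path_length(g, path)
            if lengths_seen and length > lengths_seen[-1] and len(lengths_seen) >= k:
                break
            if v in path:
                if length not in lengths_seen:
                    lengths_seen.append(length)
                if length in lengths_seen[:k]:
                    found.append(tuple(path))
    except nx.NetworkXNoPath:  # pragma: no cover - raised lazily by generator
        return []
    return found


def sample_paths(
    g: nx.Graph, k: int = 1, max_ties: int = MAX_TIES_PER_VERTEX
) -> list[ReactionPath]:
    """Union of shortest-through-v paths over every vertex, deduplicated."""
    seen: dict[tuple, ReactionPath] = {}
    for v in sorted(g.nodes):
        for path in shortest_paths_through(g, v, k=k, max_ties=max_ties):
            seen.setdefault(path.keys, path)
    return sorted(seen.values(), key=lambda pth: (pth.length, pth.keys))


def extract_minimal_subnetwork(g: nx.Graph, paths: Sequence[ReactionPath]) -> nx.Graph:
    """Drop all edges off the sampled paths; keep the R/P component.

    Raises when the sampled paths leave reactant and product in different
    components (an inconsistent path set).
    """
    r, p = g.graph["reactant"], g.graph["product"]
    keep_edges = set()
    for path in paths:
        for a, b in zip(path.keys, path.keys[1:]):
            keep_edges.add((a, b) if a < b else (b, a))
    sub = nx.Graph(reactant=r, product=p)
    for key in (r, p):
        sub.add_node(key, **g.nodes[key])
    for a, b in keep_edges:
        sub.add_node(a, **g.nodes[a])
        sub.add_node(b, **g.nodes[b])
        sub.add_edge(a, b, **g.edges[a, b])
    comp = nx.node_connected_component(sub, r) if r in sub else {r}
    if p not in comp:
        raise ValueError("reactant and product are disconnected in the sampled subnetwork")
    return sub.subgraph(comp).copy()


def rank_paths_topq(paths: Sequence[ReactionPath], q: float) -> list[ReactionPath]:
    """Keep the shortest ceil(q * n) distinct paths (ties at the cutoff kept).

    Ranks are 1-based in (length, lexicographic key) order; tied lengths
    share a percentile: 100 * (paths no longer than L) / n.
    """
    if not 0 < q <= 1:
        raise ValueError("top fraction must be in (0, 1]")
    if not paths:
        return []
    ordered = sorted(paths, key=lambda pth: (pth.length, pth.keys))
    n = len(ordered)
    k = math.ceil(q * n)
    cutoff = ordered[k - 1].length
    lengths = [pth.length for pth in ordered]
    kept = []
    for rank, path in enumerate(ordered, start=1):
        if path.length > cutoff:
            break
        share = 100.0 * sum(1 for L in lengths if L <= path.length) / n
        kept.append(ReactionPath(path.keys, path.length, rank=rank, percentile=share))
    return kept


def path_percentile(paths: Sequence[ReactionPath], keys: Sequence) -> float | None:
    """Percentile of the path with the given vertex sequence, or None."""
    ordered = sorted(paths, key=lambda pth: (pth.length, pth.keys))
    n = len(ordered)
    target = tuple(keys)
    for path in ordered:
        if path.keys == target:
            return 100.0 * sum(1 for q in ordered if q.length <= path.length) / n
    return None


def edge_frequency_ranking(
    paths: Sequence[ReactionPath], g: nx.Graph
) -> list[tuple[tuple, int]]:
    """Edges ordered by how often sampled paths traverse them.

    Most frequent first; ties broken by ascending weight, then
    lexicographically.  This is the prioritization order for expensive
    per-edge refinements (e.g. transition-state searches).
    """
    counts: dict[tuple, int] = {}
    for path in paths:
        for a, b in zip(path.keys, path.keys[1:]):
            e = (a, b) if a < b else (b, a)
            counts[e] = counts.get(e, 0) + 1
    return sorted(
        counts.items(),
        key=lambda item: (-item[1], g.edges[item[0]]["weight"], item[0]),
    )


def kinetic_filter(
    g: nx.Graph,
    e_tol: float,
    endo_threshold: float,
    reference_energy: float | None = None,
) -> nx.Graph:
    """Energy-based vertex/edge pruning of a network with known energies.

    Vertices above E(R) + ``e_tol`` are dropped; edges whose uphill energy
    difference -- in the direction away from the reactant by hop distance,
    toward the higher-energy endpoint when equidistant -- exceeds
    ``endo_threshold`` are dropped; isolated vertices are then removed.
    The reactant and product vertices are always retained.
    """
    r, p = g.graph["reactant"], g.graph["product"]
    energies = {}
    for key, data in g.nodes(data=True):
        e = data["state"].energy
        if e is None:
            name = key.short() if hasattr(key, "short") else key
            raise ValueError(f"missing energy for vertex {name}")
        energies[key] = e
    if reference_energy is None:
        reference_energy = energies[r]

    out = g.copy()
    for key in list(out.nodes):
        if key in (r, p):
            continue
        if energies[key] > reference_energy + e_tol:
            out.remove_node(key)

    hops = nx.single_source_shortest_path_length(out, r) if r in out else {}
    for a, b in list(out.edges):
        da, db = hops.get(a), hops.get(b)
        if da is None or db is None:
            hi, lo = (a, b) if energies[a] >= energies[b] else (b, a)
        elif da == db:
            hi, lo = (a, b) if energies[a] >= energies[b] else (b, a)
        else:
            hi, lo = (b, a) if db > da else (a, b)
        uphill = energies[hi] - energies[lo]
        if uphill > endo_threshold:
            out.remove_edge(a, b)

    for key in list(out.nodes):
        if key not in (r, p) and out.degree(key) == 0:
            out.remove_node(key)
    return out


def remove_edge_and_paths(
    g: nx.Graph, paths: Sequence[ReactionPath], edge: tuple
) -> tuple[nx.Graph, list[ReactionPath]]:
    """Drop an edge and every sampled path traversing it."""
    a, b = edge
    if not g.has_edge(a, b):
        raise ValueError("edge not in network")
    out = g.copy()
    out.remove_edge(a, b)
    hit = {(a, b), (b, a)}
    kept = [
        path
        for path in paths
        if not any((x, y) in hit for x, y in zip(path.keys, path.keys[1:]))
    ]
    return out, kept
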