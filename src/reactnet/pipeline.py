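"""End-to-end pipeline: input -> enumeration -> screens -> network -> paths.

Stages mirror the method's flow: the reactant and product are converted to
AC matrices; intermediates are generated combinatorially and screened for
chemical plausibility; an energy screen (E <= E(R) + E_tol) and the ellipse
criterion CD(R,I) + CD(I,P) <= CD(R,P) + delta prune the state set; the
survivors become a CD-weighted network from which shortest reactant-product
paths are sampled per vertex, ranked, and condensed into the minimal
subnetwork.  Optional energy-based graph filters and the edge-frequency
prioritization order support downstream refinement.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import io as rio
from .acmatrix import CanonicalKey
from .atoms import AtomList
from .chemdist import CDCache, cd_min, ellipse_filter
from .config import RunConfig
from .conversions import EnumerationConfig
from .enumeration import EnumerationResult, SpeciesState, enumerate_intermediates
from .fixtures import get_fixture
from .network import (
    NetworkConfig,
    ReactionPath,
    build_network,
    edge_frequency_ranking,
    extract_minimal_subnetwork,
    kinetic_filter,
    rank_paths_topq,
    sample_paths,
)
from .perception import (
    BondIncrementEvaluator,
    ExternalProcessEvaluator,
    PerceptionConfig,
    Perceiver,
    StateScreens,
    screen_energy,
    to_smiles,
)

log = logging.getLogger("reactnet")

STAGES = ("enumerate", "energy", "ellipse", "network", "paths")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineResult:
    """Artifact bundle of one run."""

    config: RunConfig
    atoms: AtomList
    r_state: SpeciesState
    p_state: SpeciesState
    enumeration: EnumerationResult | None = None
    states_after_energy: list[SpeciesState] = field(default_factory=list)
    states_after_ellipse: list[SpeciesState] = field(default_factory=list)
    network: nx.Graph | None = None
    sampled_paths: list[ReactionPath] = field(default_factory=list)
    ranked_paths: list[ReactionPath] = field(default_factory=list)
    minimal: nx.Graph | None = None
    filtered: nx.Graph | None = None
    edge_priority: list = field(default_factory=list)
    cd_cache: CDCache | None = None
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def _load_system(cfg: RunConfig):
    if cfg.fixture is not None:
        fx = get_fixture(cfg.fixture)
        atoms = fx.atom_list()
        if cfg.active is not None or cfg.catalyst:
            atoms = atoms.with_flags(
                active=cfg.active if cfg.active is not None else atoms.active_indices,
                catalyst=cfg.catalyst or atoms.catalyst_indices,
            )
        charge = fx.charge if cfg.charge is None else cfg.charge
        ring = fx.ring_bounds if cfg.ring_max == 0 and cfg.ring_min == 0 else (cfg.ring_min, cfg.ring_max)
        return atoms, fx.reactant_matrix(), fx.product_matrix(), charge, ring

    atoms, r_mat, r_charge = rio.load_structures(cfg.reactant, cfg.active, cfg.catalyst)
    atoms_p, p_raw, _ = rio.load_structures(cfg.product)
    # map the product onto the reactant's atom order via the CD-optimal mapping
    res = cd_min(r_mat, p_raw, atoms, atoms_p, time_limit=cfg.cd_time_limit)
    perm = np.asarray(res.mapping)
    p_mat = p_raw[np.ix_(perm, perm)]
    charge = r_charge if cfg.charge is None else cfg.charge
    return atoms, r_mat, p_mat, charge, (cfg.ring_min, cfg.ring_max)


def run_pipeline(cfg: RunConfig, stop_after: str | None = None) -> PipelineResult:
    """Execute the pipeline, optionally stopping after a named stage."""
    cfg.validate()
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    t_start = time.perf_counter()

    try:
        atoms, r_mat, p_mat, charge, ring_bounds = _load_system(cfg)
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    enum_cfg = EnumerationConfig(
        max_form=cfg.max_form,
        max_break=cfg.max_break,
        molecularity=cfg.molecularity,
        max_cycles=cfg.max_cycles,
        inflight_ellipse=cfg.inflight_ellipse,
        ring_bounds=ring_bounds,
        e_tol=cfg.e_tol,
        delta=cfg.delta,
    )
    perception_cfg = PerceptionConfig(
        total_charge=charge,
        charge_bound=cfg.charge_bound,
        max_extra_ion_pairs=cfg.max_extra_ion_pairs,
        ring_bounds=ring_bounds,
        metal_max_coordination=cfg.metal_max_coordination,
    )
    screens = StateScreens(atoms, perception_cfg)

    # -- Step 2: combinatorial generation -----------------------------------
    t0 = time.perf_counter()
    extra = None
    if cfg.inflight_ellipse:
        extra = _inflight_ellipse_screen(atoms, r_mat, p_mat, cfg)
    try:
        enumeration = enumerate_intermediates(r_mat, atoms, enum_cfg, screens, extra)
    except Exception as exc:
        raise PipelineError("enumerate", exc) from exc
    if not enumeration.states:
        raise PipelineError("enumerate", "the reactant state fails the plausibility screens")

    keyer = enumeration.keyer
    r_key = keyer.key(r_mat)
    p_key = keyer.key(p_mat)
    if p_key not in enumeration.states:
        warnings.warn("designated product was not reached by enumeration; adding it as a vertex")
        enumeration.states[p_key] = SpeciesState(np.asarray(p_mat, dtype=np.int8), atoms, p_key, cycle=-1)
    r_state = enumeration.states[r_key]
    p_state = enumeration.states[p_key]

    result = PipelineResult(cfg, atoms, r_state, p_state, enumeration)
    result.counts["atoms"] = len(atoms)
    result.counts["active_atoms"] = len(atoms.active_indices)
    result.counts["cycles"] = len(enumeration.cycle_counts) - 1
    result.counts["intermediates"] = len(enumeration.states)
    result.timings["enumerate"] = time.perf_counter() - t0
    log.info(
        "enumeration: %d species in %d cycles (%d matrices visited)",
        len(enumeration.states),
        result.counts["cycles"],
        enumeration.n_matrices_visited,
    )
    for i, c in enumerate(enumeration.cycle_counts):
        log.info("  cycle %d: %d new species", i, c)

    perceiver = screens.perceiver
    for s in enumeration.states.values():
        assignment = perceiver.assign_bond_orders(s.matrix, atoms)
        if assignment is not None:
            s.smiles = to_smiles(assignment, atoms)
    if stop_after == "enumerate":
        return _finish(result, t_start)

    # -- energy screen -------------------------------------------------------
    t0 = time.perf_counter()
    evaluator = (
        ExternalProcessEvaluator(cfg.evaluator_command)
        if cfg.evaluator_command
        else BondIncrementEvaluator()
    )
    try:
        e_ref = float(evaluator(r_state))
        survivors = screen_energy(
            enumeration.states.values(),
            e_ref,
            cfg.e_tol,
            evaluator,
            always_keep=(r_state, p_state),
        )
    except Exception as exc:
        raise PipelineError("energy", exc) from exc
    result.states_after_energy = survivors
    result.counts["after_energy"] = len(survivors)
    result.timings["energy"] = time.perf_counter() - t0
    log.info("energy screen (E_tol=%g): %d -> %d", cfg.e_tol, len(enumeration.states), len(survivors))
    if stop_after == "energy":
        return _finish(result, t_start)

    # -- Step 3: ellipse criterion and network ------------------------------
    t0 = time.perf_counter()
    cd_cache = CDCache(atoms, basis=cfg.cd_basis, time_limit=cfg.cd_time_limit)
    result.cd_cache = cd_cache
    try:
        inside = ellipse_filter(survivors, r_state, p_state, cfg.delta, cd_cache)
    except Exception as exc:
        raise PipelineError("ellipse", exc) from exc
    result.states_after_ellipse = inside
    result.counts["cd_rp"] = cd_cache(r_state, p_state)
    result.counts["after_ellipse"] = len(inside)
    result.timings["ellipse"] = time.perf_counter() - t0
    log.info("ellipse (delta=%d, CD(R,P)=%d): %d -> %d", cfg.delta, result.counts["cd_rp"], len(survivors), len(inside))
    if stop_after == "ellipse":
        return _finish(result, t_start)

    t0 = time.perf_counter()
    net_cfg = NetworkConfig(
        max_form=cfg.max_form,
        max_break=cfg.max_break,
        molecularity=cfg.molecularity,
    )
    try:
        g = build_network(inside, r_key, p_key, cd_cache, net_cfg)
    except Exception as exc:
        raise PipelineError("network", exc) from exc
    result.network = g
    result.counts["network_vertices"] = g.number_of_nodes()
    result.counts["network_edges"] = g.number_of_edges()
    result.timings["network"] = time.perf_counter() - t0
    log.info("network: (N_V, N_E) = (%d, %d)", g.number_of_nodes(), g.number_of_edges())
    if stop_after == "network":
        return _finish(result, t_start)

    # -- path sampling, ranking, minimal subnetwork -------------------------
    t0 = time.perf_counter()
    try:
        sampled = sample_paths(g, k=cfg.yen_k, max_ties=cfg.max_ties_per_vertex)
        ranked = rank_paths_topq(sampled, cfg.top_q)
        minimal = extract_minimal_subnetwork(g, ranked)
    except Exception as exc:
        raise PipelineError("paths", exc) from exc
    result.sampled_paths = sampled
    result.ranked_paths = ranked
    result.minimal = minimal
    result.edge_priority = edge_frequency_ranking(ranked, g)
    result.counts["sampled_paths"] = len(sampled)
    result.counts["kept_paths"] = len(ranked)
    result.counts["minimal_vertices"] = minimal.number_of_nodes()
    result.counts["minimal_edges"] = minimal.number_of_edges()
    result.timings["paths"] = time.perf_counter() - t0
    log.info(
        "paths: %d sampled, %d kept (top %.0f%%); minimal (N_V, N_E) = (%d, %d)",
        len(sampled),
        len(ranked),
        100 * cfg.top_q,
        minimal.number_of_nodes(),
        minimal.number_of_edges(),
    )

    # -- optional Step 4 graph-level energy filters -------------------------
    if cfg.endo_threshold is not None:
        try:
            result.filtered = kinetic_filter(minimal, cfg.e_tol, cfg.endo_threshold)
        except Exception as exc:
            raise PipelineError("kinetic_filter", exc) from exc
        result.counts["filtered_vertices"] = result.filtered.number_of_nodes()
        result.counts["filtered_edges"] = result.filtered.number_of_edges()

    return _finish(result, t_start)


def _inflight_ellipse_screen(atoms, r_mat, p_mat, cfg: RunConfig):
    """Ellipse criterion applied during enumeration (optional accelerator)."""
    from .acmatrix import CanonicalKeyer

    keyer = CanonicalKeyer(atoms)
    r_probe = SpeciesState(np.asarray(r_mat, dtype=np.int8), atoms, keyer.key(r_mat), 0)
    p_probe = SpeciesState(np.asarray(p_mat, dtype=np.int8), atoms, keyer.key(p_mat), 0)
    cache = CDCache(atoms, basis=cfg.cd_basis, time_limit=cfg.cd_time_limit)
    threshold = cache(r_probe, p_probe) + cfg.delta

    def screen(a) -> bool:
        probe = SpeciesState(np.asarray(a, dtype=np.int8), atoms, keyer.key(a), 0)
        return cache(r_probe, probe) + cache(probe, p_probe) <= threshold

    return screen


def _check_regressions(cfg: RunConfig, result: PipelineResult) -> None:
    if cfg.fixture is None:
        return
    expected = get_fixture(cfg.fixture).expected
    mismatches = []
    for key, want in expected.items():
        got = result.counts.get(key)
        if key == "hb_percentile" or got is None:
            continue
        if got != want:
            mismatches.append(f"{key}: expected {want}, got {got}")
    if mismatches:
        message = f"fixture {cfg.fixture!r} regression mismatches: " + "; ".join(mismatches)
        if cfg.strict:
            raise PipelineError("regression", message)
        warnings.warn(message)


def _finish(result: PipelineResult, t_start: float) -> PipelineResult:
    result.timings["total"] = time.perf_counter() - t_start
    cfg = result.config
    _check_regressions(cfg, result)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write = result.outputs
        states = list(result.enumeration.states.values())
        rio.write_states_csv(states, out / "states.csv")
        write["states"] = out / "states.csv"
        if result.states_after_ellipse and result.cd_cache is not None:
            rio.write_distance_csv(
                result.states_after_ellipse, result.cd_cache, out / "distances.csv"
            )
            write["distances"] = out / "distances.csv"
        if result.network is not None:
            rio.write_network_csv(result.network, out / "network_edges.csv")
            rio.write_network_graphml(result.network, out / "network.graphml")
            write["network_edges"] = out / "network_edges.csv"
            write["network_graphml"] = out / "network.graphml"
        if result.minimal is not None:
            rio.write_network_graphml(result.minimal, out / "minimal_subnetwork.graphml")
            write["minimal_graphml"] = out / "minimal_subnetwork.graphml"
        if result.ranked_paths and result.network is not None:
            rio.write_paths_json(result.ranked_paths, result.network, out / "paths.json")
            write["paths"] = out / "paths.json"
        import json

        (out / "counts.json").write_text(json.dumps(result.counts, indent=1))
        write["counts"] = out / "counts.json"
    return result
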