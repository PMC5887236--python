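"""Chemical plausibility screening of enumerated states.

An AC matrix only records which atoms touch; whether the state is a sensible
collection of molecules is decided here by lifting the connectivity to an
integer bond-order assignment.  The search maximizes satisfied standard
valences (octets), then minimizes total |formal charge|, subject to a
per-atom charge bound and a global charge-separation budget: the summed
|formal charge| may not exceed |system charge| plus two per allowed extra
ion pair (default: no extra pairs, i.e. no spontaneous zwitterions).
States with no feasible assignment are rejected, as are molecules whose
ring count (cyclomatic number) falls outside the configured bounds.

Metal-containing molecules bypass the octet rule: the metal is screened by a
maximum coordination number, its bonds count as single bonds toward ligand
valences, and the complex is treated as overall neutral.  This mirrors the
practical difficulty of assigning formal charges across metal-ligand bonds.

The module also defines the energy-evaluation contract used by every energy
filter, a built-in additive bond-increment surrogate evaluator, and an
external-process adapter for attaching real electronic-structure backends.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .acmatrix import decompose_components
from .atoms import METALS, AtomList, UnknownElementError, atomic_number

# allowed (valence -> formal charges) per element, closed-shell model
VALENCE_CHARGES: dict[str, dict[int, tuple[int, ...]]] = {
    "H": {1: (0,), 0: (-1, 1)},
    "C": {4: (0,), 3: (-1, 1)},
    "N": {3: (0,), 4: (1,), 2: (-1,)},
    "O": {2: (0,), 1: (-1,), 3: (1,)},
    "F": {1: (0,), 0: (-1,)},
    "Cl": {1: (0,), 0: (-1,)},
    "Br": {1: (0,), 0: (-1,)},
    "I": {1: (0,), 0: (-1,)},
    "S": {2: (0,), 4: (0,), 6: (0,), 1: (-1,), 3: (1,)},
    "P": {3: (0,), 5: (0,), 4: (1,)},
    "B": {3: (0,), 4: (-1,)},
    "Si": {4: (0,)},
}

STANDARD_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1,
    "S": 2, "P": 3, "B": 3, "Si": 4,
}

MAX_BOND_ORDER = 3

#: molecules whose textbook Lewis structure is a charge-separated octet
#: (dative bonding); they count as carrying no net charge separation.
#: keyed by (sorted symbols, edge count); values: per-atom charge by symbol
DATIVE_MOLECULES = {
    (("C", "O"), 1): {"C": -1, "O": 1},  # carbon monoxide [C-]#[O+]
}


def _max_valence(symbol: str) -> int:
    return max(VALENCE_CHARGES[symbol])


@dataclass
class PerceptionConfig:
    """Settings of the plausibility screens.

    total_charge
        net charge of the whole system (e).
    charge_bound
        maximum |formal charge| on any single atom (default 1).
    max_extra_ion_pairs
        each extra pair adds 2 to the admissible total |formal charge|
        beyond |total_charge| (default 0).
    ring_bounds
        inclusive (min, max) cyclomatic number per molecule; max None
        leaves rings unbounded.
    metal_max_coordination
        coordination-number cap replacing the valence screen for metals.
    """

    total_charge: int = 0
    charge_bound: int = 1
    max_extra_ion_pairs: int = 0
    ring_bounds: tuple[int, int | None] = (0, 0)
    metal_max_coordination: int = 6


@dataclass
class BondOrderAssignment:
    """Feasible bond orders + formal charges for one state."""

    orders: np.ndarray               # symmetric int matrix, >=1 exactly where AC==1
    charges: np.ndarray              # per-atom formal charge (e)
    valences: np.ndarray             # per-atom sum of bond orders
    components: list[tuple[int, ...]]
    octets: int                      # atoms at standard valence with charge 0
    total_abs_charge: int

    @property
    def total_charge(self) -> int:
        return int(self.charges.sum())


_Quality = tuple  # (total |q|, -octets, orders tuple) — smaller is better


def _component_options(
    symbols: tuple[str, ...],
    edges: tuple[tuple[int, int], ...],
    cfg: PerceptionConfig,
) -> dict[int, tuple[_Quality, tuple[int, ...], tuple[int, ...]]]:
    """All achievable net charges of one molecule.

    Returns ``charge -> (quality, edge orders, atom charges)`` with the best
    quality per charge; empty dict means no feasible assignment exists.
    Metal-containing molecules report charge 0 only (see module docstring).
    """
    n = len(symbols)
    for sym in symbols:
        if sym not in VALENCE_CHARGES and sym not in METALS:
            raise UnknownElementError(f"no valence model for element {sym!r}")

    dative = DATIVE_MOLECULES.get((tuple(sorted(symbols)), len(edges)))
    if dative is not None:
        charges = tuple(dative[s] for s in symbols)
        orders = tuple(MAX_BOND_ORDER for _ in edges)
        return {0: ((0, 0, orders), orders, charges)}

    metal = [i for i, s in enumerate(symbols) if s in METALS]
    degree = np.zeros(n, dtype=int)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    for m in metal:
        if degree[m] > cfg.metal_max_coordination:
            return {}

    is_metal = [s in METALS for s in symbols]
    # atoms in the coordination sphere: their formal charge is free (the
    # metal-ligand bonding is ill-defined), remote atoms obey normal rules
    coordinated = {
        e[k] for e in edges for k in (0, 1) if is_metal[e[1 - k]] and not is_metal[e[k]]
    }
    maxval = [0 if is_metal[i] else _max_valence(symbols[i]) for i in range(n)]
    # edges adjacent to a metal are fixed single bonds; so are edges where
    # either end cannot exceed valence 1 (e.g. any X-H bond)
    variable = [
        e for e in edges
        if not (is_metal[e[0]] or is_metal[e[1]]) and maxval[e[0]] > 1 and maxval[e[1]] > 1
    ]
    valence = degree.copy()  # start with all bonds at order 1
    orders = {e: 1 for e in edges}
    best: dict[int, tuple[_Quality, tuple[int, ...], tuple[int, ...]]] = {}

    def leaf():
        # per-atom charge options for the settled valences
        option_lists: list[list[tuple[int, int, int]]] = []  # (q, |q|, -octet)
        for i in range(n):
            if is_metal[i]:
                option_lists.append([(0, 0, 0)])
                continue
            allowed = VALENCE_CHARGES[symbols[i]].get(int(valence[i]))
            if not allowed:
                return
            octet = int(valence[i]) == STANDARD_VALENCE.get(symbols[i])
            if i in coordinated:
                # coordination sphere: any tabulated charge, at no budget cost
                q = min(allowed, key=abs)
                option_lists.append([(q, 0, -1 if (q == 0 and octet) else 0)])
                continue
            opts = [
                (q, abs(q), -1 if (q == 0 and octet) else 0)
                for q in allowed
                if abs(q) <= cfg.charge_bound
            ]
            if not opts:
                return
            option_lists.append(opts)
        order_vec = tuple(orders[e] for e in edges)
        # DP over atoms: net charge -> (|q| sum, -octets, charges)
        acc: dict[int, tuple[int, int, tuple[int, ...]]] = {0: (0, 0, ())}
        for opts in option_lists:
            nxt: dict[int, tuple[int, int, tuple[int, ...]]] = {}
            for tot, (absq, octs, qs) in acc.items():
                for q, aq, negoct in opts:
                    key = tot + q
                    cand = (absq + aq, octs + negoct, qs + (q,))
                    if key not in nxt or cand < nxt[key]:
                        nxt[key] = cand
            acc = nxt
        for tot, (absq, negocts, qs) in acc.items():
            quality: _Quality = (absq, negocts, order_vec)
            if tot not in best or quality < best[tot][0]:
                best[tot] = (quality, order_vec, qs)

    def dfs(k: int):
        if k == len(variable):
            leaf()
            return
        i, j = variable[k]
        # unassigned edges contribute 0 extra at minimum, so only the
        # current valences constrain the branch
        for extra in range(0, MAX_BOND_ORDER):
            valence[i] += extra
            valence[j] += extra
            if valence[i] <= maxval[i] and valence[j] <= maxval[j]:
                orders[(i, j)] = 1 + extra
                dfs(k + 1)
            valence[i] -= extra
            valence[j] -= extra
        orders[(i, j)] = 1

    # the all-single start may already bust a cap (e.g. carbon with 5 bonds);
    # raising orders only increases valences, so that is terminal
    if all(is_metal[i] or degree[i] <= maxval[i] for i in range(n)):
        dfs(0)
    if metal and best:
        # the metal absorbs net formal charge: report the complex as neutral;
        # remote-atom |q| (already excluding the coordination sphere) still
        # counts toward the charge-separation budget
        return {0: min(best.values())}
    return best


def _component_key(symbols: tuple[str, ...], edges: tuple[tuple[int, int], ...]):
    return (symbols, edges)


class Perceiver:
    """Bond-order perception with per-molecule caching."""

    def __init__(self, cfg: PerceptionConfig | None = None):
        self.cfg = cfg or PerceptionConfig()
        self._cache: dict = {}

    def _options_for(self, symbols, edges):
        key = _component_key(symbols, edges)
        if key not in self._cache:
            self._cache[key] = _component_options(symbols, edges, self.cfg)
        return self._cache[key]

    def assign_bond_orders(
        self, a: np.ndarray, atoms: AtomList, total_charge: int | None = None
    ) -> BondOrderAssignment | None:
        """Feasible bond-order + formal-charge assignment, or None.

        The per-molecule searches are combined so that the component net
        charges sum to the system charge within the charge-separation
        budget; unknown elements raise :class:`UnknownElementError` rather
        than rejecting.
        """
        cfg = self.cfg
        if total_charge is None:
            total_charge = cfg.total_charge
        a = np.asarray(a)
        comps = decompose_components(a)
        budget = abs(total_charge) + 2 * cfg.max_extra_ion_pairs

        per_comp = []
        for idx, sub in comps:
            symbols = tuple(atoms[i].symbol for i in idx)
            edges = tuple(
                (int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(sub, k=1)))
            )
            options = self._options_for(symbols, edges)
            if not options:
                return None
            per_comp.append((idx, edges, options))

        # DP across molecules on (net charge) minimizing (sum |q|, -octets)
        acc: dict[int, tuple[int, int, tuple]] = {0: (0, 0, ())}
        for _, _, options in per_comp:
            nxt: dict[int, tuple[int, int, tuple]] = {}
            for tot, (absq, negoct, picks) in acc.items():
                for c, (quality, order_vec, qs) in options.items():
                    key = tot + c
                    cand_abs = absq + quality[0]
                    if cand_abs > budget:
                        continue
                    cand = (cand_abs, negoct + quality[1], picks + ((c, order_vec, qs),))
                    if key not in nxt or cand[:2] < nxt[key][:2]:
                        nxt[key] = cand
            acc = nxt
        if total_charge not in acc:
            return None
        absq, negoct, picks = acc[total_charge]

        n = len(atoms)
        orders = np.zeros((n, n), dtype=int)
        charges = np.zeros(n, dtype=int)
        for (idx, edges, _), (_, order_vec, qs) in zip(per_comp, picks):
            for (i, j), o in zip(edges, order_vec):
                gi, gj = idx[i], idx[j]
                orders[gi, gj] = orders[gj, gi] = o
            for local, q in enumerate(qs):
                charges[idx[local]] = q
        valences = orders.sum(axis=1)
        return BondOrderAssignment(
            orders=orders,
            charges=charges,
            valences=valences,
            components=[idx for idx, _, _ in per_comp],
            octets=-negoct,
            total_abs_charge=absq,
        )


def assign_bond_orders(
    a: np.ndarray, atoms: AtomList, total_charge: int, cfg: PerceptionConfig | None = None
) -> BondOrderAssignment | None:
    """Stateless convenience wrapper around :class:`Perceiver`."""
    cfg = cfg or PerceptionConfig(total_charge=total_charge)
    return Perceiver(cfg).assign_bond_orders(a, atoms, total_charge)


def screen_valence_charge(
    assignment: BondOrderAssignment | None,
    atoms: AtomList,
    cfg: PerceptionConfig | None = None,
) -> bool:
    """Accept an assignment whose charges and valences respect the model.

    ``None`` (no feasible assignment) is rejected outright.  Assignments
    produced by :func:`assign_bond_orders` pass by construction; the check
    guards externally supplied ones.
    """
    if assignment is None:
        return False
    cfg = cfg or PerceptionConfig()
    for i, atom in enumerate(atoms):
        if atom.symbol in METALS:
            if assignment.orders[i].astype(bool).sum() > cfg.metal_max_coordination:
                return False
            continue
        q = int(assignment.charges[i])
        if abs(q) > cfg.charge_bound:
            return False
        allowed = VALENCE_CHARGES.get(atom.symbol, {}).get(int(assignment.valences[i]), ())
        if q not in allowed:
            return False
    return True


def ring_counts(a: np.ndarray) -> list[int]:
    """Cyclomatic number (edges - atoms + 1) of each molecule."""
    out = []
    for idx, sub in decompose_components(a):
        n_edges = int(np.triu(sub, k=1).sum())
        out.append(n_edges - len(idx) + 1)
    return out


def screen_ring_count(a: np.ndarray, bounds: tuple[int, int | None]) -> bool:
    """Accept a state whose per-molecule ring counts are within ``bounds``."""
    lo, hi = bounds
    for r in ring_counts(a):
        if r < lo or (hi is not None and r > hi):
            return False
    return True


class StateScreens:
    """Ring + valence/charge screens bundled for the enumeration loop."""

    def __init__(self, atoms: AtomList, cfg: PerceptionConfig | None = None):
        self.atoms = atoms
        self.cfg = cfg or PerceptionConfig()
        self.perceiver = Perceiver(self.cfg)

    def __call__(self, a: np.ndarray) -> bool:
        if not screen_ring_count(a, self.cfg.ring_bounds):
            return False
        return self.perceiver.assign_bond_orders(a, self.atoms) is not None

    def max_degrees(self) -> np.ndarray:
        """Hard per-atom degree caps implied by the valence model.

        A non-metal atom can never carry more bonds than its maximum
        allowed valence; metals are capped by the coordination number.
        Used by the enumeration loop to prune formations that could not
        survive this screen.
        """
        caps = []
        for atom in self.atoms:
            if atom.symbol in METALS:
                caps.append(self.cfg.metal_max_coordination)
            else:
                caps.append(_max_valence(atom.symbol))
        return np.asarray(caps, dtype=int)


# ---------------------------------------------------------------------------
# SMILES emission

_BOND_TYPES = None


def _rdkit_bond_types():
    global _BOND_TYPES
    if _BOND_TYPES is None:
        from rdkit import Chem

        _BOND_TYPES = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
        }
    return _BOND_TYPES


def to_smiles(
    assignment: BondOrderAssignment, atoms: AtomList
) -> list[str]:
    """Canonical SMILES per molecule of an accepted assignment.

    Molecules whose bonding defies SMILES (typically metal complexes with
    unusual coordination) are flagged with a leading ``!`` followed by their
    formula; such states keep their graph-only identity.
    """
    from rdkit import Chem

    bond_types = _rdkit_bond_types()
    out = []
    for idx in assignment.components:
        has_metal = any(atoms[i].symbol in METALS for i in idx)
        mol = Chem.RWMol()
        for i in idx:
            at = Chem.Atom(atoms[i].symbol)
            at.SetFormalCharge(int(assignment.charges[i]))
            if has_metal:
                at.SetNoImplicit(True)
            mol.AddAtom(at)
        local = {g: k for k, g in enumerate(idx)}
        for a_i in idx:
            for a_j in idx:
                if a_j > a_i and assignment.orders[a_i, a_j]:
                    mol.AddBond(local[a_i], local[a_j], bond_types[int(assignment.orders[a_i, a_j])])
        try:
            m = mol.GetMol()
            Chem.SanitizeMol(m)
            bare_h = any(
                atoms[i].symbol == "H" and not int(assignment.orders[i].sum()) for i in idx
            )
            if not has_metal and not bare_h:
                m = Chem.RemoveHs(m)
            out.append(Chem.MolToSmiles(m))
        except Exception:
            counts = Counter(atoms[i].symbol for i in idx)
            formula = "".join(
                f"{s}{c}" if c > 1 else s for s, c in sorted(counts.items())
            )
            out.append("!" + formula)
    return out


def smiles_to_graph(smiles: str) -> tuple[list[str], np.ndarray]:
    """Parse SMILES back to (element symbols, AC matrix) with explicit H."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    n = mol.GetNumAtoms()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    a = np.zeros((n, n), dtype=np.int8)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        a[i, j] = a[j, i] = 1
    return symbols, a


# ---------------------------------------------------------------------------
# Energy evaluation contract


class EnergyEvaluator(Protocol):
    """Contract: deterministic total energy (kcal/mol) of a state.

    Energies of a multi-molecule state must equal the sum over its
    molecules; only differences between states are ever used.
    """

    name: str

    def __call__(self, state) -> float: ...


#: additive increments in kcal/mol per bonded element pair (order-independent)
BOND_INCREMENTS: dict[frozenset, float] = {
    frozenset({"H"}): 104.0,
    frozenset({"H", "C"}): 99.0,
    frozenset({"H", "N"}): 93.0,
    frozenset({"H", "O"}): 111.0,
    frozenset({"H", "S"}): 87.0,
    frozenset({"H", "F"}): 135.0,
    frozenset({"H", "Cl"}): 103.0,
    frozenset({"H", "Br"}): 88.0,
    frozenset({"H", "I"}): 71.0,
    frozenset({"C"}): 85.0,
    frozenset({"C", "N"}): 75.0,
    frozenset({"C", "O"}): 95.0,
    frozenset({"C", "S"}): 65.0,
    frozenset({"C", "F"}): 116.0,
    frozenset({"C", "Cl"}): 81.0,
    frozenset({"C", "Br"}): 68.0,
    frozenset({"C", "I"}): 52.0,
    frozenset({"N"}): 40.0,
    frozenset({"N", "O"}): 50.0,
    frozenset({"O"}): 40.0,
    frozenset({"F"}): 37.0,
    frozenset({"Cl"}): 58.0,
    frozenset({"Br"}): 46.0,
    frozenset({"I"}): 36.0,
    frozenset({"I", "Cl"}): 50.0,
    frozenset({"I", "Br"}): 42.0,
    frozenset({"Br", "Cl"}): 52.0,
    frozenset({"Co", "H"}): 55.0,
    frozenset({"Co", "C"}): 35.0,
    frozenset({"Co", "O"}): 30.0,
}

DEFAULT_INCREMENT = 60.0


class BondIncrementEvaluator:
    """Additive bond-increment surrogate energy model.

    E(state) = -sum over bonds of a per-element-pair stabilization, so bond
    breaking costs energy and bond making releases it.  The model is a crude
    but deterministic stand-in used for testing energy-dependent filters; it
    ignores bond orders, strain, conformers and electronics, so absolute
    numbers are meaningless — only coarse differences matter.
    """

    name = "bond-increment-surrogate"

    def __init__(self, table: dict | None = None, default: float = DEFAULT_INCREMENT):
        self.table = dict(BOND_INCREMENTS)
        if table:
            self.table.update(table)
        self.default = default

    def __call__(self, state) -> float:
        a = np.asarray(state.matrix)
        atoms = state.atoms
        e = 0.0
        for i, j in zip(*np.nonzero(np.triu(a, k=1))):
            pair = frozenset({atoms[int(i)].symbol, atoms[int(j)].symbol})
            e -= self.table.get(pair, self.default)
        return e


class ExternalProcessEvaluator:
    """Run an external executable per state to obtain its energy.

    The executable is invoked as ``command payload.xyz result.txt`` where the
    payload holds element symbols and 3D coordinates (embedded with RDKit
    ETKDG when no geometry is known) and the result file must contain a
    single line parsable as a float: the total energy in kcal/mol.
    """

    def __init__(self, command: str, name: str = "external"):
        self.command = command
        self.name = name

    def __call__(self, state) -> float:
        xyz = embed_xyz(state)
        with tempfile.TemporaryDirectory() as tmp:
            payload = Path(tmp) / "payload.xyz"
            result = Path(tmp) / "result.txt"
            payload.write_text(xyz)
            subprocess.run(
                [*self.command.split(), str(payload), str(result)],
                check=True,
            )
            return float(result.read_text().strip().splitlines()[0])


def embed_xyz(state) -> str:
    """Best-effort 3D embedding of a state as an XYZ block (optional hook)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    a = np.asarray(state.matrix)
    atoms = state.atoms
    mol = Chem.RWMol()
    for atom in atoms:
        rd = Chem.Atom(atom.symbol)
        rd.SetNoImplicit(True)
        mol.AddAtom(rd)
    for i, j in zip(*np.nonzero(np.triu(a, k=1))):
        mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    m = mol.GetMol()
    try:
        Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
        AllChem.EmbedMolecule(m, randomSeed=0xC0FFEE & 0x7FFFFFFF)
        conf = m.GetConformer()
        coords = [conf.GetAtomPosition(i) for i in range(m.GetNumAtoms())]
    except Exception:
        coords = [(float(i), 0.0, 0.0) for i in range(len(atoms))]
    lines = [str(len(atoms)), "reactnet state"]
    for atom, p in zip(atoms, coords):
        x, y, z = (p.x, p.y, p.z) if hasattr(p, "x") else p
        lines.append(f"{atom.symbol} {x:.4f} {y:.4f} {z:.4f}")
    return "\n".join(lines) + "\n"


def screen_energy(
    states: Iterable,
    e_reference: float,
    e_tol: float,
    evaluator: EnergyEvaluator,
    always_keep: Sequence = (),
    on_error: str = "drop",
) -> list:
    """Keep states with E <= E_reference + E_tol (inclusive boundary).

    Surviving states get their ``energy`` attribute recorded.  Evaluator
    failures drop the state with a warning unless ``on_error="keep"``.
    States in ``always_keep`` (e.g. the designated reactant and product)
    are retained regardless, with their energy recorded when computable.
    """
    keep_ids = {id(s) for s in always_keep}
    kept = []
    for state in states:
        try:
            energy = float(evaluator(state))
            state.energy = energy
        except Exception as exc:  # pragma: no cover - backend-specific
            if id(state) in keep_ids or on_error == "keep":
                kept.append(state)
            else:
                warnings.warn(f"energy evaluation failed for state {state.key}: {exc}")
            continue
        if id(state) in keep_ids or energy <= e_reference + e_tol:
            kept.append(state)
    return kept
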