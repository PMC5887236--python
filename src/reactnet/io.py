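"""Structure input (SMILES / SDF / XYZ) and artifact export.

Atom indexing convention: atoms are numbered 0-based in the order they
appear in the concatenated input (heavy atoms in input order, explicit
hydrogens appended per parent atom, as RDKit emits them).  Active-atom and
catalyst-atom indices in configurations refer to this order.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .atoms import COVALENT_RADII, AtomList
from .network import ReactionPath

XYZ_CUTOFF_FACTOR = 1.2


def graph_from_smiles(smiles: str) -> tuple[list[str], np.ndarray, int]:
    """(symbols, AC matrix, net charge) from a dot-separated SMILES state."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    n = mol.GetNumAtoms()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    a = np.zeros((n, n), dtype=np.int8)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        a[i, j] = a[j, i] = 1
    charge = sum(at.GetFormalCharge() for at in mol.GetAtoms())
    return symbols, a, charge


def graph_from_sdf(path: str | Path) -> tuple[list[str], np.ndarray, int]:
    """Concatenate all records of an SDF into one block-diagonal state."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    symbols: list[str] = []
    blocks: list[np.ndarray] = []
    charge = 0
    for rec, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparsable SDF record {rec} in {path}")
        mol = Chem.AddHs(mol)
        n = mol.GetNumAtoms()
        a = np.zeros((n, n), dtype=np.int8)
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            a[i, j] = a[j, i] = 1
        symbols.extend(at.GetSymbol() for at in mol.GetAtoms())
        charge += sum(at.GetFormalCharge() for at in mol.GetAtoms())
        blocks.append(a)
    if not blocks:
        raise ValueError(f"no records in {path}")
    total = sum(b.shape[0] for b in blocks)
    full = np.zeros((total, total), dtype=np.int8)
    off = 0
    for b in blocks:
        full[off : off + b.shape[0], off : off + b.shape[0]] = b
        off += b.shape[0]
    return symbols, full, charge


def graph_from_xyz(
    path: str | Path, cutoff_factor: float = XYZ_CUTOFF_FACTOR
) -> tuple[list[str], np.ndarray, int]:
    """Perceive bonds from XYZ coordinates via covalent radii.

    Two atoms bond when their distance is below ``cutoff_factor`` times the
    sum of their covalent radii.  Charge information is not present in XYZ;
    0 is returned.
    """
    lines = Path(path).read_text().strip().splitlines()
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    xyz = np.asarray(coords)
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            ri = COVALENT_RADII.get(symbols[i], 1.5)
            rj = COVALENT_RADII.get(symbols[j], 1.5)
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d <= cutoff_factor * (ri + rj):
                a[i, j] = a[j, i] = 1
    return symbols, a, 0


def load_structures(
    source: str | Path,
    active=None,
    catalyst=None,
    cutoff_factor: float = XYZ_CUTOFF_FACTOR,
) -> tuple[AtomList, np.ndarray, int]:
    """Build (atom list, AC matrix, net charge) from SMILES or a file path."""
    text = str(source)
    p = Path(text)
    if p.suffix.lower() in (".sdf", ".mol"):
        symbols, a, charge = graph_from_sdf(p)
    elif p.suffix.lower() == ".xyz":
        symbols, a, charge = graph_from_xyz(p, cutoff_factor)
    else:
        symbols, a, charge = graph_from_smiles(text)
    atoms = AtomList.from_symbols(symbols, active=active, catalyst=catalyst)
    return atoms, a, charge


# ---------------------------------------------------------------------------
# exports


def write_states_csv(states, path: str | Path) -> None:
    rows = [
        {
            "key": s.key.short(),
            "cycle": s.cycle,
            "n_components": len(s.components()),
            "smiles": ".".join(s.smiles) if s.smiles else "",
            "energy": "" if s.energy is None else f"{s.energy:.6f}",
        }
        for s in states
    ]
    pd.DataFrame(rows, columns=["key", "cycle", "n_components", "smiles", "energy"]).to_csv(
        path, index=False
    )


def read_states_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def write_distance_csv(states, cd_cache, path: str | Path) -> None:
    labels = [s.key.short() for s in states]
    n = len(states)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = cd_cache(states[i], states[j])
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path)


def read_distance_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_mappings_json(states, cd_cache, path: str | Path) -> None:
    """Optimal atom mappings as index pairs, one record per state pair."""
    records = []
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            res = cd_cache.distance(states[i], states[j])
            records.append(
                {
                    "from": states[i].key.short(),
                    "to": states[j].key.short(),
                    "cd": res.value,
                    "status": res.status,
                    "mapping": [[k, int(v)] for k, v in enumerate(res.mapping)],
                }
            )
    Path(path).write_text(json.dumps(records, indent=1))


def _edge_rows(g: nx.Graph):
    for a, b, data in sorted(g.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
        a, b = (a, b) if a < b else (b, a)
        yield {
            "source": a.short(),
            "target": b.short(),
            "weight": data["weight"],
            "formed": ";".join(f"{i}-{j}" for i, j in data.get("formed", ())),
            "broken": ";".join(f"{i}-{j}" for i, j in data.get("broken", ())),
        }


def write_network_csv(g: nx.Graph, path: str | Path) -> None:
    pd.DataFrame(
        list(_edge_rows(g)), columns=["source", "target", "weight", "formed", "broken"]
    ).to_csv(path, index=False)


def read_network_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def write_network_graphml(g: nx.Graph, path: str | Path) -> None:
    out = nx.Graph()
    out.graph["reactant"] = g.graph["reactant"].short()
    out.graph["product"] = g.graph["product"].short()
    for key, data in g.nodes(data=True):
        state = data.get("state")
        out.add_node(
            key.short(),
            cycle=-1 if state is None else state.cycle,
            smiles="" if state is None or not state.smiles else ".".join(state.smiles),
        )
    for a, b, data in g.edges(data=True):
        out.add_edge(a.short(), b.short(), weight=int(data["weight"]))
    nx.write_graphml(out, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_paths_json(paths, g: nx.Graph, path: str | Path) -> None:
    records = []
    for p in paths:
        smiles = []
        for key in p.keys:
            state = g.nodes[key].get("state")
            smiles.append(".".join(state.smiles) if state is not None and state.smiles else "")
        records.append(
            {
                "vertices": [k.short() for k in p.keys],
                "smiles": smiles,
                "length": p.length,
                "rank": p.rank,
                "percentile": p.percentile,
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))


def read_paths_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def write_states_sdf(states, perceiver, path: str | Path) -> None:
    """SDF export with perceived bond orders (no 3D coordinates)."""
    from rdkit import Chem

    bond_types = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for s in states:
            assignment = perceiver.assign_bond_orders(s.matrix, s.atoms)
            if assignment is None:
                continue
            mol = Chem.RWMol()
            for i, atom in enumerate(s.atoms):
                rd = Chem.Atom(atom.symbol)
                rd.SetFormalCharge(int(assignment.charges[i]))
                rd.SetNoImplicit(True)
                mol.AddAtom(rd)
            for i, j in zip(*np.nonzero(np.triu(s.matrix, k=1))):
                mol.AddBond(int(i), int(j), bond_types[int(assignment.orders[i, j])])
            m = mol.GetMol()
            try:
                Chem.SanitizeMol(m)
            except Exception:
                pass
            m.SetProp("_Name", s.key.short())
            writer.write(m)
    finally:
        writer.close()
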