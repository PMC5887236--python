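"""Run configuration: one structured record driving the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Either ``fixture`` names a built-in system, or ``reactant``/``product``
    give SMILES strings or SDF/MOL/XYZ paths.  Atom indices (``active``,
    ``catalyst``) are 0-based over the concatenated reactant input order.
    """

    fixture: str | None = None
    reactant: str | None = None
    product: str | None = None
    charge: int | None = None
    active: tuple[int, ...] | None = None
    catalyst: tuple[int, ...] = ()

    max_form: int = 2
    max_break: int = 2
    molecularity: int = 2
    max_cycles: int | None = None
    inflight_ellipse: bool = False

    ring_min: int = 0
    ring_max: int | None = 0
    charge_bound: int = 1
    max_extra_ion_pairs: int = 0
    metal_max_coordination: int = 6

    e_tol: float = 20.0
    delta: int = 6
    endo_threshold: float | None = None
    top_q: float = 0.5
    yen_k: int = 1
    #: deterministic cap on equidistant-path enumeration per vertex
    max_ties_per_vertex: int = 1000

    #: chemical distances between enumerated states are evaluated on the
    #: active-atom sub-matrices by default: every bond change lives there
    #: (spectator bonds are frozen during enumeration), and the tiny basis
    #: keeps the assignment MILP exact and fast.  "all" minimizes over
    #: permutations of the complete atom list instead.
    cd_basis: str = "active"
    cd_time_limit: float = 10.0

    evaluator_command: str | None = None
    output_dir: str | None = None
    strict: bool = False

    def validate(self) -> None:
        if self.fixture is None and (self.reactant is None or self.product is None):
            raise ValueError("provide a fixture name or both reactant and product inputs")
        for src in (self.reactant, self.product):
            if src is not None:
                p = Path(str(src))
                if p.suffix.lower() in (".sdf", ".mol", ".xyz") and not p.exists():
                    raise FileNotFoundError(f"input file not found: {src}")
        if not 0 < self.top_q <= 1:
            raise ValueError("top_q must be in (0, 1]")
        if self.delta < 0:
            raise ValueError("digression factor must be >= 0")
        if self.cd_basis not in ("all", "active"):
            raise ValueError("cd_basis must be 'all' or 'active'")


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("active", "catalyst"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {}
    for f in fields(RunConfig):
        value = getattr(cfg, f.name)
        if isinstance(value, tuple):
            value = list(value)
        data[f.name] = value
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
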