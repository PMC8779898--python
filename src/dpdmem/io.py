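"""Run configuration, trajectory and restart I/O.

Configurations are YAML mappings with a fixed schema (unknown keys are
rejected).  Attractions may be given either as dimensionless ``epsilon``
values or as raw conservative strengths ``a`` -- but not both for the same
pair.  Trajectories are written as extended XYZ (human readable, truncated
precision); restarts use a NumPy archive that round-trips the full state
bit-exactly.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .builder import SystemRecipe
from .engine import RunParams, Schedule, ScheduleEvent, SimulationBox, SystemState
from .model import BEAD_TYPES, BEADS, A_SS, A_WE, EpsilonSpec, InteractionTable, epsilon_to_a

__all__ = [
    "RunConfig",
    "load_config",
    "write_frame",
    "read_xyz_frames",
    "save_restart",
    "load_restart",
]

_PAIR_NAMES = {
    "E-E": ("E", "E"),
    "E-H_B": ("E", "H_B"),
    "E-S": ("E", "S"),
}
_PAIR_BASELINES = {"E-E": A_WE, "E-H_B": A_WE, "E-S": A_SS}
_EPS_KEYS = {"ee": "E-E", "em": "E-H_B", "es": "E-S"}


@dataclass
class RunConfig:
    """Validated run configuration with all defaults resolved."""

    box: SimulationBox
    n_major: int = 0
    n_minor: int = 0
    n_idp: int = 0
    n_linker_lipid: int = 0
    idp_backbone: int = 6
    rho: float = 3.0
    eps: EpsilonSpec = field(default_factory=EpsilonSpec)
    dt: float = 0.02
    lam: float = 0.5
    kBT: float = 1.0
    gamma: float = 4.5
    seed: int = 0
    steps: int = 0
    backend: str = "reference"
    schedule: list[ScheduleEvent] = field(default_factory=list)
    output_interval: int = 1000
    trajectory: str | None = None
    observables: str | None = None

    def recipe(self) -> SystemRecipe:
        return SystemRecipe(
            box=self.box,
            n_major=self.n_major,
            n_minor=self.n_minor,
            n_idp=self.n_idp,
            n_linker_lipid=self.n_linker_lipid,
            idp_backbone=self.idp_backbone,
            rho=self.rho,
            seed=self.seed,
            eps=self.eps,
        )

    def params(self) -> RunParams:
        return RunParams(dt=self.dt, lam=self.lam, kBT=self.kBT, seed=self.seed, steps=self.steps)

    def table(self) -> InteractionTable:
        t = self.eps.make_table(gamma=self.gamma, kBT=self.kBT)
        return t

    def make_schedule(self) -> Schedule:
        return Schedule(sorted(self.schedule, key=lambda e: e.step))


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    extra = set(section) - allowed
    if extra:
        raise ValueError(f"unknown key(s) {sorted(extra)} in {where}; allowed: {sorted(allowed)}")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    _reject_unknown(
        raw,
        {"box", "counts", "epsilon", "a", "engine", "density", "backend", "schedule", "output"},
        "config",
    )
    if "box" not in raw:
        raise ValueError("config requires 'box: [Lx, Ly, Lz]'")
    box = SimulationBox(tuple(float(x) for x in raw["box"]))

    counts = raw.get("counts", {}) or {}
    _reject_unknown(counts, {"major", "minor", "idp", "linker_lipid", "idp_backbone"}, "counts")

    eps_raw = raw.get("epsilon", {}) or {}
    a_raw = raw.get("a", {}) or {}
    _reject_unknown(eps_raw, set(_EPS_KEYS), "epsilon")
    _reject_unknown(a_raw, set(_EPS_KEYS), "a")
    both = set(eps_raw) & set(a_raw)
    if both:
        raise ValueError(
            f"pair(s) {sorted(both)} specified both as epsilon and as raw a; pick one"
        )
    eps_vals = {}
    for key, pair_name in _EPS_KEYS.items():
        if key in eps_raw:
            eps_vals[key] = float(eps_raw[key])
        elif key in a_raw:
            eps_vals[key] = 1.0 - float(a_raw[key]) / _PAIR_BASELINES[pair_name]
        else:
            eps_vals[key] = 0.0
    eps = EpsilonSpec(eps_ee=eps_vals["ee"], eps_em=eps_vals["em"], eps_es=eps_vals["es"])

    eng = raw.get("engine", {}) or {}
    _reject_unknown(eng, {"dt", "lambda", "kBT", "gamma", "seed", "steps"}, "engine")
    steps = int(eng.get("steps", 0))

    sched_events = []
    for item in raw.get("schedule", []) or []:
        _reject_unknown(item, {"step", "frac", "pair", "a", "epsilon"}, "schedule event")
        if ("step" in item) == ("frac" in item):
            raise ValueError("schedule event needs exactly one of 'step' or 'frac'")
        step = int(item["step"]) if "step" in item else int(round(float(item["frac"]) * steps))
        pair_name = item.get("pair")
        if pair_name not in _PAIR_NAMES:
            raise ValueError(f"schedule pair must be one of {sorted(_PAIR_NAMES)}, got {pair_name!r}")
        if ("a" in item) == ("epsilon" in item):
            raise ValueError("schedule event needs exactly one of 'a' or 'epsilon'")
        a_val = (
            float(item["a"])
            if "a" in item
            else epsilon_to_a(float(item["epsilon"]), _PAIR_BASELINES[pair_name])
        )
        sched_events.append(ScheduleEvent(step, _PAIR_NAMES[pair_name], a_val))
    sched_events.sort(key=lambda e: e.step)

    out = raw.get("output", {}) or {}
    _reject_unknown(out, {"interval", "trajectory", "observables"}, "output")

    backend = raw.get("backend", "reference")
    if backend not in ("reference", "cellgraph"):
        raise ValueError(f"backend must be 'reference' or 'cellgraph', got {backend!r}")

    return RunConfig(
        box=box,
        n_major=int(counts.get("major", 0)),
        n_minor=int(counts.get("minor", 0)),
        n_idp=int(counts.get("idp", 0)),
        n_linker_lipid=int(counts.get("linker_lipid", 0)),
        idp_backbone=int(counts.get("idp_backbone", 6)),
        rho=float(raw.get("density", 3.0)),
        eps=eps,
        dt=float(eng.get("dt", 0.02)),
        lam=float(eng.get("lambda", 0.5)),
        kBT=float(eng.get("kBT", 1.0)),
        gamma=float(eng.get("gamma", 4.5)),
        seed=int(eng.get("seed", 0)),
        steps=steps,
        backend=backend,
        schedule=sched_events,
        output_interval=int(out.get("interval", 1000)),
        trajectory=out.get("trajectory"),
        observables=out.get("observables"),
    )


# ---------------------------------------------------------------------------
# trajectories (extended XYZ)


def write_frame(state: SystemState, stream, velocities: bool = False, precision: int = 9) -> None:
    """Append one extended-XYZ frame (bit-stable fixed-precision text)."""
    L = state.box.lengths
    props = "species:S:1:pos:R:3" + (":vel:R:3" if velocities else "")
    stream.write(f"{state.n}\n")
    stream.write(
        f'Lattice="{L[0]:.6f} 0.0 0.0 0.0 {L[1]:.6f} 0.0 0.0 0.0 {L[2]:.6f}" '
        f"Properties={props} step={state.step}\n"
    )
    fmt = f"%.{precision}f"
    for b in range(state.n):
        name = BEADS.name(int(state.types[b]))
        fields = [name] + [fmt % x for x in state.pos[b]]
        if velocities:
            fields += [fmt % v for v in state.vel[b]]
        stream.write(" ".join(fields) + "\n")


def read_xyz_frames(path):
    """Yield (names, positions, comment) per frame of an (extended) XYZ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                return
            n = int(header)
            comment = fh.readline().rstrip("\n")
            names = []
            pos = np.empty((n, 3))
            for b in range(n):
                parts = fh.readline().split()
                names.append(parts[0])
                pos[b] = [float(x) for x in parts[1:4]]
            yield names, pos, comment


# ---------------------------------------------------------------------------
# restarts (exact-precision container)


def save_restart(state: SystemState, path) -> None:
    """Write the complete state; load_restart round-trips it bit-exactly."""
    np.savez(
        path,
        box=state.box.array,
        pos=state.pos,
        vel=state.vel,
        force=state.force,
        types=state.types,
        mol_id=state.mol_id,
        leaflet=state.leaflet,
        bonds=state.bonds,
        bond_params=state.bond_params,
        angles=state.angles,
        angle_params=state.angle_params,
        step=np.int64(state.step),
    )


def load_restart(path) -> SystemState:
    with np.load(path) as d:
        state = SystemState(
            SimulationBox(tuple(d["box"])),
            d["pos"],
            vel=d["vel"],
            types=d["types"],
            mol_id=d["mol_id"],
            leaflet=d["leaflet"],
            bonds=d["bonds"].reshape(-1, 2),
            bond_params=d["bond_params"].reshape(-1, 2),
            angles=d["angles"].reshape(-1, 3),
            angle_params=d["angle_params"].reshape(-1, 2),
            step=int(d["step"]),
        )
        state.force = d["force"]
    return state
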