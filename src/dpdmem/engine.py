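"""Reference DPD engine: cell-list neighbor search, soft pair forces with a
pairwise thermostat, Hookean bonds, bending terms and modified velocity-Verlet
integration under full periodic boundary conditions.

Time stepping follows the Groot-Warren scheme: positions advance with the
current forces, the dissipative force is evaluated with the predicted
velocity ``v + lambda*dt*f``, and velocities complete with the mean of old
and new forces.  All randomness is a counter-based pair RNG keyed on
(pair, step, seed), which makes trajectories bitwise reproducible and lets
the cell-graph backend draw identical noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import VARIABLE_PAIRS, InteractionTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationBox",
    "SystemState",
    "RunParams",
    "ScheduleEvent",
    "Schedule",
    "ReferenceEngine",
    "pair_rng",
    "neighbor_pairs",
]


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic box; edge lengths in d0."""

    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.lengths) != 3:
            raise ValueError("box needs three edge lengths")
        for L in self.lengths:
            if L < 3.0:
                raise ValueError(
                    f"box edge {L} < 3 d0: the cell list needs >= 3 cells per axis"
                )

    @property
    def array(self) -> np.ndarray:
        return np.array(self.lengths, dtype=np.float64)

    @property
    def volume(self) -> float:
        return float(np.prod(self.array))

    def n_cells(self) -> np.ndarray:
        """Cells per axis: floor(L), so cell edges are >= 1 (the cutoff)."""
        nc = np.array([int(math.floor(L + 1e-9)) for L in self.lengths], dtype=np.int64)
        for L, n in zip(self.lengths, nc):
            if abs(L - n) > 1e-9:
                logger.info("box edge %.6g not integer; using %d cells of width %.6g", L, n, L / n)
        return nc

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        return np.mod(pos, self.array)

    def min_image(self, d: np.ndarray) -> np.ndarray:
        L = self.array
        return d - L * np.rint(d / L)


class SystemState:
    """Complete mechanical state of a system plus its bonded topology.

    Arrays: positions (wrapped into [0, L)), velocities, accumulated forces,
    bead-type indices, molecule ids and a leaflet tag (+1 upper / -1 lower /
    0 not a lipid, assigned at build time).  The bonded topology is stored
    flat: ``bonds`` (nb, 2) with parameters (k, l0) and ``angles`` (na, 3)
    with parameters (k3, phi0).
    """

    def __init__(
        self,
        box: SimulationBox,
        pos: np.ndarray,
        vel: np.ndarray | None = None,
        types: np.ndarray | None = None,
        mol_id: np.ndarray | None = None,
        leaflet: np.ndarray | None = None,
        bonds: np.ndarray | None = None,
        bond_params: np.ndarray | None = None,
        angles: np.ndarray | None = None,
        angle_params: np.ndarray | None = None,
        step: int = 0,
    ) -> None:
        n = len(pos)
        self.box = box
        self.pos = np.ascontiguousarray(pos, dtype=np.float64)
        self.vel = (
            np.zeros((n, 3)) if vel is None else np.ascontiguousarray(vel, dtype=np.float64)
        )
        self.force = np.zeros((n, 3))
        self.types = (
            np.zeros(n, dtype=np.int64) if types is None else np.ascontiguousarray(types, dtype=np.int64)
        )
        self.mol_id = (
            np.arange(n, dtype=np.int64) if mol_id is None else np.ascontiguousarray(mol_id, dtype=np.int64)
        )
        self.leaflet = (
            np.zeros(n, dtype=np.int8) if leaflet is None else np.ascontiguousarray(leaflet, dtype=np.int8)
        )
        self.bonds = (
            np.zeros((0, 2), dtype=np.int64) if bonds is None else np.ascontiguousarray(bonds, dtype=np.int64)
        )
        self.bond_params = (
            np.zeros((0, 2)) if bond_params is None else np.ascontiguousarray(bond_params, dtype=np.float64)
        )
        self.angles = (
            np.zeros((0, 3), dtype=np.int64) if angles is None else np.ascontiguousarray(angles, dtype=np.int64)
        )
        self.angle_params = (
            np.zeros((0, 2)) if angle_params is None else np.ascontiguousarray(angle_params, dtype=np.float64)
        )
        self.step = int(step)
        self._check()

    def _check(self) -> None:
        n = self.n
        for name in ("vel", "force"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
        for name in ("types", "mol_id", "leaflet"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")

    @property
    def n(self) -> int:
        return len(self.pos)

    def wrap(self) -> None:
        self.pos = self.box.wrap(self.pos)

    def total_momentum(self) -> np.ndarray:
        return self.vel.sum(axis=0)  # m = 1

    def kinetic_temperature(self) -> float:
        return float((self.vel**2).sum() / (3.0 * self.n))

    def copy(self) -> "SystemState":
        new = SystemState(
            self.box,
            self.pos.copy(),
            self.vel.copy(),
            self.types.copy(),
            self.mol_id.copy(),
            self.leaflet.copy(),
            self.bonds.copy(),
            self.bond_params.copy(),
            self.angles.copy(),
            self.angle_params.copy(),
            self.step,
        )
        new.force = self.force.copy()
        return new


@dataclass
class RunParams:
    """Integrator parameters (reduced units)."""

    dt: float = 0.02
    lam: float = 0.5
    kBT: float = 1.0
    seed: int = 0
    steps: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")


@dataclass(frozen=True)
class ScheduleEvent:
    """At ``step`` (before force evaluation) set a variable entry to ``a``."""

    step: int
    pair: tuple[str, str]
    a: float

    def __post_init__(self) -> None:
        pair = tuple(sorted(self.pair))
        if frozenset(self.pair) not in {frozenset(p) for p in VARIABLE_PAIRS}:
            raise ValueError(
                f"schedule may only toggle the variable pairs {sorted(VARIABLE_PAIRS)}, got {pair}"
            )


class Schedule:
    """Ordered interaction-toggling events; same-step events apply in list order."""

    def __init__(self, events: list[ScheduleEvent] | None = None) -> None:
        events = list(events or [])
        for prev, nxt in zip(events, events[1:]):
            if nxt.step < prev.step:
                raise ValueError("schedule trigger steps must be non-decreasing")
        self.events = events
        self._next = 0

    def reset(self) -> None:
        self._next = 0

    def apply_due(self, step: int, table: InteractionTable) -> bool:
        """Apply all events with trigger <= step; returns True if any fired."""
        fired = False
        while self._next < len(self.events) and self.events[self._next].step <= step:
            ev = self.events[self._next]
            table.set_a(ev.pair, ev.a)
            logger.info("schedule: step %d set a(%s-%s) = %g", step, ev.pair[0], ev.pair[1], ev.a)
            self._next += 1
            fired = True
        return fired


def pair_rng(i: int, j: int, step: int, seed: int) -> float:
    """Symmetric counter-based unit-variance variate for pair (i, j) at a step."""
    if i == j:
        raise ValueError("pair RNG needs two distinct beads")
    return float(_kernels.pair_rng_stream(i, j, np.array([step], dtype=np.int64), seed)[0])


def neighbor_pairs(state: SystemState, cutoff: float = 1.0) -> np.ndarray:
    """All unordered bead pairs within ``cutoff`` (minimum image), via the cell list."""
    nc = state.box.n_cells()
    pi, pj = _kernels._collect_pairs(state.pos, state.box.array, nc, cutoff)
    out = np.stack([pi, pj], axis=1)
    lo = out.min(axis=1)
    hi = out.max(axis=1)
    out = np.stack([lo, hi], axis=1)
    return out[np.lexsort((out[:, 1], out[:, 0]))]


class ReferenceEngine:
    """Single-array DPD integrator used as the ground truth backend.

    ``strict_order=True`` accumulates non-bonded pair forces in canonical
    (i, j) order so runs can be compared bitwise against the cell-graph
    backend; the default enumeration order is faster and differs only in
    floating-point summation order.
    """

    def __init__(
        self,
        state: SystemState,
        table: InteractionTable,
        params: RunParams,
        schedule: Schedule | None = None,
        strict_order: bool = False,
    ) -> None:
        table.validate()
        self.state = state
        self.table = table
        self.params = params
        self.schedule = schedule or Schedule()
        self.strict_order = strict_order
        self._nc = state.box.n_cells()
        self._initialized = False

    # -- forces -------------------------------------------------------------
    def compute_forces(self, vel_for_dissipation: np.ndarray, rng_step: int) -> np.ndarray:
        s = self.state
        f = _kernels.nonbonded_forces(
            s.pos,
            np.ascontiguousarray(vel_for_dissipation),
            s.types,
            self.table.a,
            self.table.gamma,
            self.table.sigma,
            s.box.array,
            self._nc,
            rng_step,
            self.params.seed,
            self.params.dt,
            self.strict_order,
        )
        _kernels.bond_forces(s.pos, s.bonds, s.bond_params, s.box.array, f)
        _kernels.angle_forces(s.pos, s.angles, s.angle_params, s.box.array, f)
        return f

    def initialize(self) -> None:
        """Evaluate forces for the starting configuration (rng keyed on step)."""
        if not self._initialized:
            self.schedule.apply_due(self.state.step, self.table)
            self.state.force = self.compute_forces(self.state.vel, self.state.step)
            self._initialized = True

    # -- stepping -----------------------------------------------------------
    def step(self) -> None:
        self.initialize()
        s, p = self.state, self.params
        self.schedule.apply_due(s.step, self.table)
        f_old = s.force
        s.pos += p.dt * s.vel + 0.5 * p.dt * p.dt * f_old
        s.wrap()
        v_tilde = s.vel + p.lam * p.dt * f_old
        f_new = self.compute_forces(v_tilde, s.step + 1)
        s.vel += 0.5 * p.dt * (f_old + f_new)
        s.force = f_new
        s.step += 1
        if not np.isfinite(s.pos).all():
            bad = np.flatnonzero(~np.isfinite(s.pos).all(axis=1))
            raise RuntimeError(
                f"non-finite coordinates at step {s.step} for beads {bad[:10].tolist()} "
                f"(types {s.types[bad[:10]].tolist()}); dt too large or overlapping topology"
            )

    def run(self, n_steps: int, observer=None, observe_every: int = 1000) -> None:
        """Advance ``n_steps``; call ``observer(state)`` every ``observe_every`` steps."""
        self.initialize()
        for _ in range(n_steps):
            self.step()
            if observer is not None and self.state.step % observe_every == 0:
                observer(self.state)
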