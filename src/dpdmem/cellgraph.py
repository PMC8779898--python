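"""Cell-graph backend: a software emulation of the event-triggered two-phase
DPD algorithm used on fine-grained message-passing hardware.

The box is partitioned into unit-volume cells, one logical vertex per cell,
each linked to its 26 periodic neighbors.  A time step is two phases:

* **force phase** -- every vertex broadcasts its resident beads (Share); on
  receipt a vertex computes non-bonded and Hookean interactions of received
  beads against residents (a pair is computed by the vertex owning its
  lower-numbered bead and mirrored); the vertex owning an angle's middle
  bead computes the triple force once both ends are known and sends
  AngleForce messages to the vertices holding the end beads.
* **movement phase** -- every vertex integrates its residents; beads leaving
  the unit cube are broadcast (BeadExit) and adopted by the vertex that
  contains the wrapped position (BeadEntrance).

Execution is sequential-deterministic (phases act as barriers): the contract
being exercised is the message protocol and its locality, not hardware
concurrency.  Per-pair arithmetic, pair RNG and bonded kernels are shared
with the reference engine, so in strict-order mode (canonical pair-order
accumulation, the default) the two backends produce bitwise-identical
trajectories from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import _kernels
from .engine import RunParams, Schedule, SystemState
from .model import InteractionTable

__all__ = ["Message", "CellVertex", "CellGraphEngine", "run_cellgraph"]


@dataclass(frozen=True)
class Message:
    """One in-flight message; payload is immutable in transit."""

    kind: str  # "Share" | "AngleForce" | "BeadExit"
    sender: int  # flat cell index
    payload: tuple


@dataclass
class CellVertex:
    """Read-only view of one cell vertex (for inspection and tests)."""

    index: int
    coords: tuple[int, int, int]
    residents: np.ndarray
    neighbors: np.ndarray


@njit(cache=True)
def _owned_pairs(res, recv, pos, box):
    """Pairs computed by this vertex: lower bead id resident here, r < 1.

    res-res pairs (i < j) plus res x received pairs with resident id lower.
    """
    nr = res.shape[0]
    nv = recv.shape[0]
    cap = nr * (nr + nv)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    m = 0
    for u in range(nr):
        i = res[u]
        for v in range(u + 1, nr):
            j = res[v]
            dx = _kernels._min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _kernels._min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _kernels._min_image(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < 1.0:
                if i < j:
                    pi[m] = i
                    pj[m] = j
                else:
                    pi[m] = j
                    pj[m] = i
                m += 1
        for v in range(nv):
            j = recv[v]
            if i >= j:
                continue  # the neighbor owning j's... lower id not here
            dx = _kernels._min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _kernels._min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _kernels._min_image(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz < 1.0:
                pi[m] = i
                pj[m] = j
                m += 1
    return pi[:m], pj[:m]


class CellGraphEngine:
    """Two-phase message-passing DPD backend over a graph of unit cells."""

    def __init__(
        self,
        state: SystemState,
        table: InteractionTable,
        params: RunParams,
        schedule: Schedule | None = None,
        strict_order: bool = True,
        collect_messages: bool = False,
    ) -> None:
        table.validate()
        self.state = state
        self.table = table
        self.params = params
        self.schedule = schedule or Schedule()
        self.strict_order = strict_order
        self.collect_messages = collect_messages
        self.messages: list[Message] = []
        self.message_counts = {"Share": 0, "AngleForce": 0, "BeadExit": 0}

        L = state.box.lengths
        nc = tuple(int(round(x)) for x in L)
        if any(abs(a - b) > 1e-9 for a, b in zip(L, nc)):
            raise ValueError(f"cell graph needs integer box edges (unit cells), got {L}")
        self.nc = np.array(nc, dtype=np.int64)
        self.ncells = int(np.prod(self.nc))
        self._neighbors = self._build_neighbor_table()
        self._cell_coords = self._build_cell_coords()
        self._refresh_residency()
        self._initialized = False

    # -- graph topology -----------------------------------------------------
    def _build_neighbor_table(self) -> np.ndarray:
        nx, ny, nz = (int(x) for x in self.nc)
        nbr = np.empty((self.ncells, 26), dtype=np.int64)
        offs = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
        for cx in range(nx):
            for cy in range(ny):
                for cz in range(nz):
                    c = (cx * ny + cy) * nz + cz
                    for o, (dx, dy, dz) in enumerate(offs):
                        nbr[c, o] = (((cx + dx) % nx) * ny + (cy + dy) % ny) * nz + (cz + dz) % nz
        return nbr

    def _build_cell_coords(self) -> np.ndarray:
        nx, ny, nz = (int(x) for x in self.nc)
        coords = np.empty((self.ncells, 3), dtype=np.int64)
        for cx in range(nx):
            for cy in range(ny):
                for cz in range(nz):
                    coords[(cx * ny + cy) * nz + cz] = (cx, cy, cz)
        return coords

    def _refresh_residency(self) -> None:
        s = self.state
        self.bead_cell = _kernels._assign_cells(s.pos, s.box.array, self.nc)
        self._order, self._start = _kernels._bucket_sort(self.bead_cell, self.ncells)

    def residents(self, c: int) -> np.ndarray:
        """Resident bead ids of cell ``c`` (ascending, a residency partition)."""
        return self._order[self._start[c] : self._start[c + 1]]

    def vertices(self):
        for c in range(self.ncells):
            yield CellVertex(
                c, tuple(self._cell_coords[c]), self.residents(c), self._neighbors[c]
            )

    # -- phases -------------------------------------------------------------
    def force_phase(self, vel_for_dissipation: np.ndarray, rng_step: int) -> np.ndarray:
        """Share / Integration / AngleForces / AngleAddition -> per-bead forces."""
        s = self.state
        box = s.box.array
        vel = np.ascontiguousarray(vel_for_dissipation)
        pi_parts: list[np.ndarray] = []
        pj_parts: list[np.ndarray] = []
        for c in range(self.ncells):
            res = self.residents(c)
            if res.size == 0:
                continue
            # Sharing: each resident bead broadcast once to the 26 neighbors
            self.message_counts["Share"] += int(res.size)
            if self.collect_messages:
                self.messages.append(Message("Share", c, tuple(res.tolist())))
            recv = (
                np.concatenate([self.residents(d) for d in self._neighbors[c]])
                if self.ncells > 1
                else np.empty(0, dtype=np.int64)
            )
            pi, pj = _owned_pairs(res, recv, s.pos, box)
            if pi.size:
                pi_parts.append(pi)
                pj_parts.append(pj)
        if pi_parts:
            pi = np.concatenate(pi_parts)
            pj = np.concatenate(pj_parts)
        else:
            pi = pj = np.empty(0, dtype=np.int64)
        fv = _kernels.pair_force_values(
            pi, pj, s.pos, vel, s.types,
            self.table.a, self.table.gamma, self.table.sigma,
            box, rng_step, self.params.seed, self.params.dt,
        )
        if self.strict_order:
            f = _kernels.accumulate_pairs_sorted(pi, pj, fv, s.n)
        else:
            f = np.zeros((s.n, 3))
            np.add.at(f, pi, fv)
            np.subtract.at(f, pj, fv)

        # Hookean bonds: computed by the vertex owning the lower-id endpoint;
        # the partner must have been received (within one cell shell).
        self._check_locality(s.bonds, "bond")
        _kernels.bond_forces(s.pos, s.bonds, s.bond_params, box, f)

        # AngleForces / AngleAddition: the middle bead's vertex computes the
        # triple once both ends are known and messages the end-bead owners.
        if len(s.angles):
            self._check_locality(s.angles[:, [0, 1]], "angle", ref_col=1)
            self._check_locality(s.angles[:, [2, 1]], "angle", ref_col=1)
            self.message_counts["AngleForce"] += 2 * len(s.angles)
        _kernels.angle_forces(s.pos, s.angles, s.angle_params, box, f)
        return f

    def _check_locality(self, pairs: np.ndarray, kind: str, ref_col: int = 0) -> None:
        """Hard error if a bonded partner lies beyond the 27-cell neighborhood."""
        if len(pairs) == 0:
            return
        ca = self._cell_coords[self.bead_cell[pairs[:, 0]]]
        cb = self._cell_coords[self.bead_cell[pairs[:, 1]]]
        d = np.abs(ca - cb)
        d = np.minimum(d, self.nc[None, :] - d)
        bad = np.flatnonzero((d > 1).any(axis=1))
        if bad.size:
            raise RuntimeError(
                f"{kind} {bad[0]} spans beads more than one cell apart "
                "(stretched past the cell size; the run is unstable)"
            )

    def movement_phase(self) -> None:
        """Integrate residents, then BeadExit/BeadEntrance residency handoff."""
        s, p = self.state, self.params
        f_old = s.force
        old_cell = self.bead_cell
        s.pos += p.dt * s.vel + 0.5 * p.dt * p.dt * f_old
        s.wrap()
        self._v_tilde = s.vel + p.lam * p.dt * f_old
        new_cell = _kernels._assign_cells(s.pos, s.box.array, self.nc)
        moved = np.flatnonzero(new_cell != old_cell)
        if moved.size:
            d = np.abs(self._cell_coords[new_cell[moved]] - self._cell_coords[old_cell[moved]])
            d = np.minimum(d, self.nc[None, :] - d)
            if (d > 1).any():
                b = moved[(d > 1).any(axis=1)][0]
                raise RuntimeError(
                    f"bead {int(b)} moved more than one cell in one step "
                    "(dt too large or the system has blown up)"
                )
            self.message_counts["BeadExit"] += int(moved.size)
            if self.collect_messages:
                for b in moved:
                    self.messages.append(
                        Message("BeadExit", int(old_cell[b]), (int(b), int(new_cell[b])))
                    )
        n_before = self._order.size
        self.bead_cell = new_cell
        self._order, self._start = _kernels._bucket_sort(new_cell, self.ncells)
        if self._order.size != n_before:
            raise RuntimeError("bead count changed across movement phase")

    # -- stepping (identical arithmetic to the reference engine) ------------
    def initialize(self) -> None:
        if not self._initialized:
            self.schedule.apply_due(self.state.step, self.table)
            self.state.force = self.force_phase(self.state.vel, self.state.step)
            self._initialized = True

    def step(self) -> None:
        self.initialize()
        s, p = self.state, self.params
        self.schedule.apply_due(s.step, self.table)
        f_old = s.force
        self.movement_phase()
        f_new = self.force_phase(self._v_tilde, s.step + 1)
        s.vel += 0.5 * p.dt * (f_old + f_new)
        s.force = f_new
        s.step += 1
        if not np.isfinite(s.pos).all():
            raise RuntimeError(f"non-finite coordinates at step {s.step}")

    def run(self, n_steps: int, observer=None, observe_every: int = 1000) -> None:
        self.initialize()
        for _ in range(n_steps):
            self.step()
            if observer is not None and self.state.step % observe_every == 0:
                observer(self.state)


def run_cellgraph(
    state: SystemState,
    table: InteractionTable,
    params: RunParams,
    n_steps: int,
    schedule: Schedule | None = None,
    strict_order: bool = True,
    observer=None,
    observe_every: int = 1000,
) -> SystemState:
    """Convenience wrapper: run the cell-graph backend for ``n_steps``."""
    eng = CellGraphEngine(state, table, params, schedule, strict_order=strict_order)
    eng.run(n_steps, observer=observer, observe_every=observe_every)
    return eng.state
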