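"""Initial-configuration builders.

A system is assembled in four stages: a pre-formed planar bilayer with the
minority species confined to the upper leaflet, randomly scattered
disordered proteins in the bulk, solvent fill to the target bead density
(rho d0^3 = 3), and Maxwell-Boltzmann velocities with the net momentum
removed and the kinetic temperature rescaled exactly to kBT.

The bilayer sits at the box midplane with its normal along z.  Lipids are
seeded on a snug square lattice (small in-plane jitter breaks symmetry) with
head chains pointing into the solvent and tails toward the midplane; the
soft DPD potentials tolerate the residual overlaps, which anneal within a
short equilibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SimulationBox, SystemState
from .model import (
    BEADS,
    BondTerm,
    EpsilonSpec,
    MoleculeTemplate,
    make_idp_template,
    make_linker_lipid_template,
    make_lipid_template,
)

__all__ = [
    "SystemRecipe",
    "build_bilayer",
    "scatter_idps",
    "fill_solvent",
    "assign_velocities",
    "build_system",
    "make_fixture",
    "FIXTURES",
    "flagship_recipe",
]

#: solvent exclusion half-thickness around the bilayer midplane (4 * l0)
SLAB_HALF = 2.0


@dataclass
class SystemRecipe:
    """Counts, box and parameters defining one buildable system."""

    box: SimulationBox
    n_major: int = 0
    n_minor: int = 0
    n_idp: int = 0
    n_linker_lipid: int = 0
    idp_backbone: int = 6
    rho: float = 3.0
    seed: int = 0
    eps: EpsilonSpec = field(default_factory=EpsilonSpec)

    def __post_init__(self) -> None:
        for name in ("n_major", "n_minor", "n_idp", "n_linker_lipid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")

    @property
    def n_lipids(self) -> int:
        return self.n_major + self.n_minor + self.n_linker_lipid

    @property
    def minority_fraction(self) -> float:
        return (self.n_minor + self.n_linker_lipid) / self.n_lipids

    @property
    def target_beads(self) -> int:
        return int(round(self.rho * self.box.volume))


def flagship_recipe(seed: int = 0) -> SystemRecipe:
    """The full-size two-component membrane: 1989 major + 397 minor lipids,
    397 B6 proteins, 40 x 40 x 48 box at density 3 (230,400 beads)."""
    return SystemRecipe(
        box=SimulationBox((40.0, 40.0, 48.0)),
        n_major=1989,
        n_minor=397,
        n_idp=397,
        idp_backbone=6,
        seed=seed,
    )


class _Assembler:
    """Accumulates molecule instances into flat SystemState arrays."""

    def __init__(self, box: SimulationBox) -> None:
        self.box = box
        self.pos: list[np.ndarray] = []
        self.types: list[np.ndarray] = []
        self.mol: list[np.ndarray] = []
        self.leaflet: list[np.ndarray] = []
        self.bonds: list[np.ndarray] = []
        self.bond_params: list[np.ndarray] = []
        self.angles: list[np.ndarray] = []
        self.angle_params: list[np.ndarray] = []
        self._n = 0
        self._next_mol = 0

    def add_molecule(self, template: MoleculeTemplate, coords: np.ndarray, leaflet: int = 0) -> None:
        nb = template.n_beads
        if coords.shape != (nb, 3):
            raise ValueError("coordinate block does not match template size")
        off = self._n
        self.pos.append(self.box.wrap(np.asarray(coords, dtype=np.float64)))
        self.types.append(template.type_indices().astype(np.int64))
        self.mol.append(np.full(nb, self._next_mol, dtype=np.int64))
        self.leaflet.append(np.full(nb, leaflet, dtype=np.int8))
        if template.bonds:
            self.bonds.append(np.array([[b.i + off, b.j + off] for b in template.bonds], dtype=np.int64))
            self.bond_params.append(np.array([[b.k, b.l0] for b in template.bonds]))
        if template.angles:
            self.angles.append(
                np.array([[a.i + off, a.j + off, a.k + off] for a in template.angles], dtype=np.int64)
            )
            self.angle_params.append(np.array([[a.k3, a.phi0] for a in template.angles]))
        self._n += nb
        self._next_mol += 1

    def add_solvent(self, coords: np.ndarray) -> None:
        nb = len(coords)
        if nb == 0:
            return
        self.pos.append(self.box.wrap(np.asarray(coords, dtype=np.float64)))
        self.types.append(np.full(nb, BEADS.index("W"), dtype=np.int64))
        self.mol.append(np.arange(self._next_mol, self._next_mol + nb, dtype=np.int64))
        self.leaflet.append(np.zeros(nb, dtype=np.int8))
        self._n += nb
        self._next_mol += nb

    def build(self) -> SystemState:
        def cat(parts, empty_shape, dtype=np.float64):
            if not parts:
                return np.zeros(empty_shape, dtype=dtype)
            return np.concatenate(parts)

        return SystemState(
            self.box,
            cat(self.pos, (0, 3)),
            types=cat(self.types, (0,), np.int64),
            mol_id=cat(self.mol, (0,), np.int64),
            leaflet=cat(self.leaflet, (0,), np.int8),
            bonds=cat(self.bonds, (0, 2), np.int64),
            bond_params=cat(self.bond_params, (0, 2)),
            angles=cat(self.angles, (0, 3), np.int64),
            angle_params=cat(self.angle_params, (0, 2)),
        )


def _lipid_coords(x: float, y: float, z_mid: float, sign: int) -> np.ndarray:
    """Idealized coordinates for one 12-bead lipid at lattice site (x, y).

    ``sign`` is +1 for the upper leaflet (heads above the midplane), -1 for
    the lower.  Head chain vertical; the two tails hang side by side from
    head beads 3 and 4 down to the midplane.
    """
    c = np.empty((12, 3))
    head_z = [3.75, 3.25, 2.75, 2.25]
    for i, hz in enumerate(head_z):
        c[i] = (x, y, z_mid + sign * hz)
    for t, (anchor_z, dx) in enumerate(((2.75, -0.25), (2.25, 0.25))):
        for b in range(4):
            c[4 + 4 * t + b] = (x + dx, y, z_mid + sign * (anchor_z - 0.5 * (b + 1)))
    return c


def _linker_coords(x: float, y: float, z_top: float, sign: int, n: int = 32) -> np.ndarray:
    """Compact serpentine for the linker arm, stacked above the head bead.

    Rows of 8 beads at 0.45 spacing, rising 0.45 per row, so a 32-bead arm
    occupies ~3.2 x 1.4 d0 above the membrane surface regardless of box
    height.  Bent starting angles cost little (k3 = 5) and relax quickly.
    """
    c = np.empty((n, 3))
    for b in range(n):
        row, col = divmod(b, 8)
        xx = col if row % 2 == 0 else 7 - col
        c[b] = (x - 1.6 + 0.45 * xx, y, z_top + sign * 0.45 * (row + 1))
    return c


def build_bilayer(recipe: SystemRecipe) -> SystemState:
    """Pre-assembled planar bilayer, minority species in the upper leaflet only.

    Lipids split equally between leaflets; minority (and linker) lipids take
    uniformly random lattice sites in the upper leaflet, the rest fill with
    the majority species.
    """
    rng = np.random.default_rng(recipe.seed)
    box = recipe.box
    Lx, Ly, Lz = box.lengths
    z_mid = Lz / 2.0
    n_total = recipe.n_lipids
    n_lower = n_total // 2
    n_upper = n_total - n_lower
    n_minority = recipe.n_minor + recipe.n_linker_lipid
    if n_minority > n_upper:
        raise ValueError(
            f"{n_minority} minority lipids do not fit the upper leaflet ({n_upper} lipids)"
        )

    major = make_lipid_template("major")
    minor = make_lipid_template("minor")
    linker = make_linker_lipid_template()
    asm = _Assembler(box)

    def leaflet_sites(count: int) -> np.ndarray:
        if count == 0:
            return np.zeros((0, 2))
        nx = max(1, int(np.ceil(np.sqrt(count * Lx / Ly))))
        ny = int(np.ceil(count / nx))
        while nx * ny < count:
            ny += 1
        sx, sy = Lx / nx, Ly / ny
        if min(sx, sy) < 0.7:
            amin = 0.7 * 0.7 * count
            raise ValueError(
                f"{count} lipids per leaflet exceed the lattice capacity of the "
                f"{Lx} x {Ly} cross-section; need at least {amin:.0f} d0^2"
            )
        sites = np.array([(ix * sx, iy * sy) for ix in range(nx) for iy in range(ny)])
        chosen = rng.choice(len(sites), size=count, replace=False)
        jitter = rng.uniform(-0.1, 0.1, size=(count, 2))
        return sites[chosen] + jitter

    # upper leaflet: minority first on shuffled sites, then majority
    upper = leaflet_sites(n_upper)
    rng.shuffle(upper)
    idx = 0
    for _ in range(recipe.n_linker_lipid):
        x, y = upper[idx]
        idx += 1
        coords = np.vstack(
            [_lipid_coords(x, y, z_mid, +1), _linker_coords(x, y, z_mid + 3.75, +1)]
        )
        asm.add_molecule(linker, coords, leaflet=+1)
    for _ in range(recipe.n_minor):
        x, y = upper[idx]
        idx += 1
        asm.add_molecule(minor, _lipid_coords(x, y, z_mid, +1), leaflet=+1)
    for _ in range(n_upper - n_minority):
        x, y = upper[idx]
        idx += 1
        asm.add_molecule(major, _lipid_coords(x, y, z_mid, +1), leaflet=+1)
    for x, y in leaflet_sites(n_lower):
        asm.add_molecule(major, _lipid_coords(x, y, z_mid, -1), leaflet=-1)
    return asm.build()


def _grow_state(state: SystemState, asm: _Assembler) -> SystemState:
    """Concatenate newly assembled molecules onto an existing state."""
    extra = asm.build()
    merged = SystemState(
        state.box,
        np.vstack([state.pos, extra.pos]),
        vel=np.vstack([state.vel, extra.vel]),
        types=np.concatenate([state.types, extra.types]),
        mol_id=np.concatenate([state.mol_id, extra.mol_id + (state.mol_id.max(initial=-1) + 1)]),
        leaflet=np.concatenate([state.leaflet, extra.leaflet]),
        bonds=np.vstack([state.bonds, extra.bonds + state.n]).astype(np.int64),
        bond_params=np.vstack([state.bond_params, extra.bond_params]),
        angles=np.vstack([state.angles, extra.angles + state.n]).astype(np.int64),
        angle_params=np.vstack([state.angle_params, extra.angle_params]),
        step=state.step,
    )
    return merged


def _has_membrane(state: SystemState) -> bool:
    return bool(np.any(state.leaflet != 0))


def scatter_idps(
    state: SystemState,
    n_idp: int,
    template: MoleculeTemplate,
    seed: int = 0,
    max_tries: int = 2000,
) -> SystemState:
    """Insert ``n_idp`` chains at random positions/orientations in the bulk.

    Chains start as slightly perturbed straight rods (bead spacing l0) and
    are rejected if any bead falls inside the membrane slab
    (|z - Lz/2| < 4 l0); they wrap periodically in x and y.
    """
    if n_idp == 0:
        return state
    rng = np.random.default_rng(seed + 7919)
    box = state.box
    Lz = box.lengths[2]
    z_mid = Lz / 2.0
    exclude_slab = _has_membrane(state)
    nb = template.n_beads
    asm = _Assembler(box)
    for _ in range(n_idp):
        for attempt in range(max_tries):
            origin = rng.uniform(0, 1, 3) * box.array
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords = origin + 0.5 * np.arange(nb)[:, None] * direction
            coords = coords + rng.normal(scale=0.05, size=(nb, 3))
            z = coords[:, 2] % Lz
            if exclude_slab and np.any(np.abs(z - z_mid) < SLAB_HALF):
                continue
            if np.any(z > Lz) or np.any(z < 0):
                continue
            asm.add_molecule(template, coords % box.array)
            break
        else:
            raise RuntimeError(
                f"could not place chain after {max_tries} tries; the box is too small "
                "for the requested number of chains"
            )
    return _grow_state(state, asm)


def fill_solvent(state: SystemState, rho: float = 3.0, seed: int = 0) -> SystemState:
    """Add W beads (outside the membrane slab) until N = round(rho * V)."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    target = int(round(rho * state.box.volume))
    need = target - state.n
    if need < 0:
        raise ValueError(
            f"target bead count {target} below current {state.n}; lower the density or counts"
        )
    if need == 0:
        return state
    rng = np.random.default_rng(seed + 104729)
    box = state.box
    Lz = box.lengths[2]
    z_mid = Lz / 2.0
    exclude_slab = _has_membrane(state)
    coords = np.empty((need, 3))
    placed = 0
    while placed < need:
        batch = rng.uniform(0, 1, (2 * (need - placed) + 16, 3)) * box.array
        if exclude_slab:
            batch = batch[np.abs(batch[:, 2] - z_mid) >= SLAB_HALF]
        take = min(len(batch), need - placed)
        coords[placed : placed + take] = batch[:take]
        placed += take
    asm = _Assembler(box)
    asm.add_solvent(coords)
    return _grow_state(state, asm)


def assign_velocities(state: SystemState, kBT: float = 1.0, seed: int = 0) -> SystemState:
    """Maxwell-Boltzmann velocities, zero net momentum, exact kinetic kBT."""
    if state.n == 0:
        raise ValueError("cannot assign velocities to an empty state")
    rng = np.random.default_rng(seed + 15485863)
    v = rng.normal(scale=np.sqrt(kBT), size=(state.n, 3))
    v -= v.mean(axis=0)
    if state.n > 1:
        t = (v**2).sum() / (3.0 * state.n)
        v *= np.sqrt(kBT / t)
    state.vel = v
    return state


def build_system(recipe: SystemRecipe) -> SystemState:
    """Full build: bilayer -> proteins -> solvent fill -> velocities."""
    if recipe.n_lipids > 0:
        state = build_bilayer(recipe)
    else:
        state = SystemState(recipe.box, np.zeros((0, 3)))
    if recipe.n_idp > 0:
        state = scatter_idps(
            state, recipe.n_idp, make_idp_template(recipe.idp_backbone), seed=recipe.seed
        )
    state = fill_solvent(state, recipe.rho, seed=recipe.seed)
    if state.n:
        state = assign_velocities(state, seed=recipe.seed)
    return state


# ---------------------------------------------------------------------------
# deterministic test fixtures


def _fixture_pure_water(seed: int) -> SystemState:
    box = SimulationBox((8.0, 8.0, 8.0))
    state = SystemState(box, np.zeros((0, 3)))
    state = fill_solvent(state, 3.0, seed=seed)
    return assign_velocities(state, seed=seed)


def _fixture_mini_membrane(seed: int) -> SystemState:
    recipe = SystemRecipe(
        box=SimulationBox((12.0, 12.0, 16.0)), n_major=180, n_minor=36, seed=seed
    )
    return build_system(recipe)


def _fixture_dimer(seed: int) -> SystemState:
    box = SimulationBox((4.0, 4.0, 4.0))
    tmpl = MoleculeTemplate("dimer", ("W", "W"), bonds=(BondTerm(0, 1),))
    asm = _Assembler(box)
    asm.add_molecule(tmpl, np.array([[2.0, 2.0, 1.75], [2.0, 2.0, 2.25]]))
    return asm.build()


def _fixture_idp_gas(seed: int) -> SystemState:
    box = SimulationBox((8.0, 8.0, 8.0))
    state = SystemState(box, np.zeros((0, 3)))
    state = scatter_idps(state, 12, make_idp_template(6), seed=seed)
    state = fill_solvent(state, 3.0, seed=seed)
    return assign_velocities(state, seed=seed)


def _fixture_linker_mini(seed: int) -> SystemState:
    recipe = SystemRecipe(
        box=SimulationBox((10.0, 10.0, 12.0)),
        n_major=84,
        n_minor=12,
        n_linker_lipid=4,
        n_idp=10,
        seed=seed,
    )
    return build_system(recipe)


FIXTURES = {
    "pure-water-8": _fixture_pure_water,
    "mini-membrane-12x12x16": _fixture_mini_membrane,
    "two-bead-dimer": _fixture_dimer,
    "idp-gas": _fixture_idp_gas,
    "linker-mini": _fixture_linker_mini,
}

_ALIASES = {
    "pure-water-8x8x8": "pure-water-8",
    "pure-water-8³": "pure-water-8",
    "mini-membrane": "mini-membrane-12x12x16",
}


def make_fixture(name: str, seed: int = 0) -> SystemState:
    """Deterministic small systems for tests and smoke runs."""
    key = _ALIASES.get(name, name)
    try:
        factory = FIXTURES[key]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return factory(seed)
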