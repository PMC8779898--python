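"""Force-field definition and molecule templates.

The coarse-grained model lives in reduced units: lengths in the interaction
cutoff ``d0`` (~1 nm), energies in ``kBT`` and masses in the bead mass ``m = 1``.
Nine bead types make up the system:

====  =====================================================
name  role
====  =====================================================
W     solvent (one bead per water volume)
E     self-associating endcap bead of the disordered protein
B     backbone bead of the disordered protein
H_A   headgroup bead of the majority lipid
T_A   tail bead of the majority lipid
H_B   headgroup bead of the minority lipid
T_B   tail bead of the minority lipid
L     inert linker bead (linker-lipid cytoplasmic arm)
S     sticky linker bead
====  =====================================================

Non-bonded interactions are soft conservative repulsions of strength
``a_ij`` (kBT/d0) with a shared dissipative constant ``gamma = 4.5``.  The
three entries ``a_EE``, ``a_EM`` (= E-H_B) and ``a_ES`` are the control
parameters of the study; every other entry is fixed.  Attractions are
quoted as dimensionless ``eps = (baseline - a) / baseline`` with baseline
``a_WE = 25`` for the endcap pairs and ``a_SS = 30`` for the endcap-sticky
pair, so ``eps = 0`` means "no net attraction relative to solvent" and
``eps = 1`` a very strong attraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BEAD_TYPES",
    "BeadTypeTable",
    "InteractionTable",
    "BondTerm",
    "AngleTerm",
    "MoleculeTemplate",
    "EpsilonSpec",
    "a_to_epsilon",
    "epsilon_to_a",
    "sigma_from_gamma",
    "make_lipid_template",
    "make_idp_template",
    "make_linker_lipid_template",
]

#: canonical bead-type ordering; indices are stable for a whole run
BEAD_TYPES = ("W", "E", "B", "H_A", "T_A", "H_B", "T_B", "L", "S")

#: interaction cutoff in reduced units
CUTOFF = 1.0
#: dissipative strength shared by all pairs
GAMMA = 4.5
#: Hookean spring constant (kBT/d0^2) and rest length (d0)
BOND_K = 128.0
BOND_L0 = 0.5
#: bending stiffness of lipid tails and of polymer chains (kBT)
K3_TAIL = 15.0
K3_CHAIN = 5.0
#: baselines for the dimensionless attraction parameters
A_WE = 25.0
A_SS = 30.0

#: variable entries of the conservative matrix, by type-pair name
VARIABLE_PAIRS = {("E", "E"), ("E", "H_B"), ("E", "S")}


class BeadTypeTable:
    """Bidirectional name <-> index mapping for the nine bead types."""

    names = BEAD_TYPES

    def __init__(self) -> None:
        self._index = {name: i for i, name in enumerate(BEAD_TYPES)}

    def __len__(self) -> int:
        return len(BEAD_TYPES)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown bead type {name!r}; valid: {BEAD_TYPES}") from None

    def name(self, index: int) -> str:
        return BEAD_TYPES[index]


BEADS = BeadTypeTable()


def a_to_epsilon(a: float, baseline: float) -> float:
    """Dimensionless attraction ``(baseline - a) / baseline``.

    Zero means the pair interacts like either bead does with solvent; one is
    maximal attraction (``a = 0``).  Values are negative when ``a`` exceeds
    the baseline (net repulsion), which is allowed but outside the explored
    range ``0 <= eps <= 1``.
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return (baseline - a) / baseline


def epsilon_to_a(eps: float, baseline: float) -> float:
    """Inverse of :func:`a_to_epsilon`: ``a = baseline * (1 - eps)``."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    if eps > 1:
        raise ValueError(f"eps must be <= 1 (a >= 0), got {eps}")
    return baseline * (1.0 - eps)


def sigma_from_gamma(gamma: float, kBT: float = 1.0) -> float:
    """Random-force amplitude from the fluctuation-dissipation relation.

    ``sigma^2 = 2 * gamma * kBT`` ties the random-force strength to the
    dissipative strength so the pair thermostat samples the canonical
    ensemble at temperature ``kBT``.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    if kBT <= 0:
        raise ValueError(f"kBT must be positive, got {kBT}")
    return math.sqrt(2.0 * gamma * kBT)


def _fixed_a_matrix() -> np.ndarray:
    """Fixed conservative strengths; variable entries at their neutral values.

    Neutral means eps = 0: a_EE = a_EM = 25 (solvent baseline a_WE) and
    a_ES = 30 (sticky-sticky baseline a_SS).
    """
    rows = {
        "W": {"W": 25},
        "E": {"W": 25, "E": 25},
        "B": {"W": 23, "E": 25, "B": 25},
        "H_A": {"W": 30, "E": 30, "B": 30, "H_A": 30},
        "T_A": {"W": 75, "E": 35, "B": 35, "H_A": 35, "T_A": 10},
        "H_B": {"W": 30, "E": 25, "B": 30, "H_A": 30, "T_A": 35, "H_B": 30},
        "T_B": {"W": 75, "E": 35, "B": 35, "H_A": 35, "T_A": 10, "H_B": 35, "T_B": 10},
        "L": {"W": 30, "E": 30, "B": 30, "H_A": 30, "T_A": 35, "H_B": 30, "T_B": 35, "L": 30},
        "S": {"W": 30, "E": 30, "B": 30, "H_A": 30, "T_A": 35, "H_B": 30, "T_B": 35, "L": 30, "S": 30},
    }
    n = len(BEAD_TYPES)
    a = np.zeros((n, n))
    for ti, row in rows.items():
        for tj, val in row.items():
            i, j = BEADS.index(ti), BEADS.index(tj)
            a[i, j] = a[j, i] = float(val)
    return a


class InteractionTable:
    """Symmetric conservative / dissipative strength matrices.

    ``a`` holds the conservative strengths in kBT/d0; ``gamma`` the
    dissipative strengths (filled with the single value 4.5).  Only the
    three variable entries (E-E, E-H_B, E-S) may be changed during a run,
    via :meth:`set_a` or :meth:`set_epsilon`.
    """

    def __init__(self, gamma: float = GAMMA, kBT: float = 1.0) -> None:
        self.a = _fixed_a_matrix()
        n = len(BEAD_TYPES)
        self.gamma = np.full((n, n), float(gamma))
        self.kBT = float(kBT)

    # -- epsilon plumbing ---------------------------------------------------
    _BASELINES = {("E", "E"): A_WE, ("E", "H_B"): A_WE, ("E", "S"): A_SS}

    @staticmethod
    def _canon(pair: tuple[str, str]) -> tuple[str, str]:
        pair = tuple(sorted(pair, key=BEADS.index))
        return pair  # type: ignore[return-value]

    def set_a(self, pair: tuple[str, str], value: float) -> None:
        """Set one of the variable conservative entries (and its transpose)."""
        pair = self._canon(pair)
        if pair not in self._BASELINES:
            raise ValueError(
                f"pair {pair} is fixed by the force field; only "
                f"{sorted(self._BASELINES)} may be modified"
            )
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"conservative strength must be finite and >= 0, got {value}")
        i, j = (BEADS.index(t) for t in pair)
        self.a[i, j] = self.a[j, i] = float(value)

    def set_epsilon(self, pair: tuple[str, str], eps: float) -> None:
        pair = self._canon(pair)
        if pair not in self._BASELINES:
            raise ValueError(f"no epsilon baseline for pair {pair}")
        self.set_a(pair, epsilon_to_a(eps, self._BASELINES[pair]))

    def get_epsilon(self, pair: tuple[str, str]) -> float:
        pair = self._canon(pair)
        i, j = (BEADS.index(t) for t in pair)
        return a_to_epsilon(self.a[i, j], self._BASELINES[pair])

    @property
    def sigma(self) -> np.ndarray:
        """Random-force amplitudes, entrywise sqrt(2 * gamma * kBT)."""
        return np.sqrt(2.0 * self.gamma * self.kBT)

    def validate(self) -> None:
        if not np.allclose(self.a, self.a.T):
            raise ValueError("conservative matrix must be symmetric")
        if not np.allclose(self.gamma, self.gamma.T):
            raise ValueError("dissipative matrix must be symmetric")
        if not (np.isfinite(self.a).all() and (self.a >= 0).all()):
            raise ValueError("conservative strengths must be finite and >= 0")
        if not (np.isfinite(self.gamma).all() and (self.gamma >= 0).all()):
            raise ValueError("dissipative strengths must be finite and >= 0")

    def copy(self) -> "InteractionTable":
        new = InteractionTable.__new__(InteractionTable)
        new.a = self.a.copy()
        new.gamma = self.gamma.copy()
        new.kBT = self.kBT
        return new


@dataclass(frozen=True)
class BondTerm:
    """Hookean spring between beads ``i`` and ``j`` of a template/system."""

    i: int
    j: int
    k: float = BOND_K
    l0: float = BOND_L0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")


@dataclass(frozen=True)
class AngleTerm:
    """Bending term ``k3 * (1 - cos(phi - phi0))`` on triple (i, j, k), vertex j.

    ``phi`` is the angle between consecutive bond vectors (0 = straight
    chain), so ``phi0 = 0`` favours extended conformations.
    """

    i: int
    j: int
    k: int
    k3: float
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle beads must be pairwise distinct")


@dataclass
class MoleculeTemplate:
    """Topology of one molecular species: bead types, bonds and angles."""

    name: str
    bead_types: tuple[str, ...]
    bonds: tuple[BondTerm, ...] = ()
    angles: tuple[AngleTerm, ...] = ()

    def __post_init__(self) -> None:
        self.bead_types = tuple(self.bead_types)
        self.bonds = tuple(self.bonds)
        self.angles = tuple(self.angles)
        n = len(self.bead_types)
        for t in self.bead_types:
            BEADS.index(t)  # raises on unknown type
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond {b} out of range for {n} beads")
        bonded = {frozenset((b.i, b.j)) for b in self.bonds}
        for ang in self.angles:
            if not all(0 <= x < n for x in (ang.i, ang.j, ang.k)):
                raise ValueError(f"angle {ang} out of range for {n} beads")
            if (
                frozenset((ang.i, ang.j)) not in bonded
                or frozenset((ang.j, ang.k)) not in bonded
            ):
                raise ValueError(f"angle {ang} does not span two bonds")

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    def type_indices(self) -> np.ndarray:
        return np.array([BEADS.index(t) for t in self.bead_types], dtype=np.int32)

    def is_connected(self) -> bool:
        n = self.n_beads
        if n == 1:
            return True
        ii = [b.i for b in self.bonds] + [b.j for b in self.bonds]
        jj = [b.j for b in self.bonds] + [b.i for b in self.bonds]
        g = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
        ncomp, _ = connected_components(g, directed=False)
        return ncomp == 1

    def is_tree(self) -> bool:
        return self.is_connected() and len(self.bonds) == self.n_beads - 1

    # -- config-block (de)serialization ------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "beads": " ".join(self.bead_types),
            "bonds": [[b.i, b.j, b.k, b.l0] for b in self.bonds],
            "angles": [[a.i, a.j, a.k, a.k3, a.phi0] for a in self.angles],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeTemplate":
        return cls(
            name=d["name"],
            bead_types=tuple(d["beads"].split()),
            bonds=tuple(BondTerm(int(i), int(j), float(k), float(l0)) for i, j, k, l0 in d["bonds"]),
            angles=tuple(
                AngleTerm(int(i), int(j), int(k), float(k3), float(p0))
                for i, j, k, k3, p0 in d["angles"]
            ),
        )


@dataclass
class EpsilonSpec:
    """The three dimensionless attraction parameters of a run.

    ``eps_ee`` couples endcaps to each other (baseline a_WE = 25),
    ``eps_em`` endcaps to minority-lipid headgroups (baseline a_WE = 25),
    ``eps_es`` endcaps to sticky linker beads (baseline a_SS = 30).
    """

    eps_ee: float = 0.0
    eps_em: float = 0.0
    eps_es: float = 0.0

    def make_table(self, gamma: float = GAMMA, kBT: float = 1.0) -> InteractionTable:
        table = InteractionTable(gamma=gamma, kBT=kBT)
        table.set_epsilon(("E", "E"), self.eps_ee)
        table.set_epsilon(("E", "H_B"), self.eps_em)
        table.set_epsilon(("E", "S"), self.eps_es)
        return table


# ---------------------------------------------------------------------------
# molecule templates


def make_lipid_template(species: str, include_junction_angles: bool = True) -> MoleculeTemplate:
    """Two-tailed lipid: 4-bead linear head, two 4-bead tails.

    Beads 0-3 are the head chain; tail one (beads 4-7) hangs off head bead 3
    (index 2) and tail two (beads 8-11) off head bead 4 (index 3) -- the
    final two adjacent head beads.  Tails carry stiff bending terms
    (k3 = 15); by default the head-tail junction triple of each tail is
    included so the tails have a defined orientation relative to the head
    (``include_junction_angles=False`` restricts angles to all-tail triples).
    """
    if species == "major":
        h, t = "H_A", "T_A"
    elif species == "minor":
        h, t = "H_B", "T_B"
    else:
        raise ValueError(f"species must be 'major' or 'minor', got {species!r}")
    types = (h,) * 4 + (t,) * 8
    bonds = [BondTerm(0, 1), BondTerm(1, 2), BondTerm(2, 3)]
    for anchor, start in ((2, 4), (3, 8)):
        bonds.append(BondTerm(anchor, start))
        bonds += [BondTerm(i, i + 1) for i in range(start, start + 3)]
    angles = []
    for anchor, start in ((2, 4), (3, 8)):
        chain = [anchor] if include_junction_angles else []
        chain += list(range(start, start + 4))
        angles += [
            AngleTerm(chain[i], chain[i + 1], chain[i + 2], K3_TAIL)
            for i in range(len(chain) - 2)
        ]
    return MoleculeTemplate(f"lipid_{species}", types, tuple(bonds), tuple(angles))


def make_idp_template(n_backbone: int) -> MoleculeTemplate:
    """Telechelic disordered protein: 4 E endcap beads, n backbone B beads, 4 E.

    The semi-flexible backbone carries k3 = 5 bending terms on every
    all-backbone triple; the endcaps are fully flexible.
    """
    if n_backbone < 1:
        raise ValueError(f"n_backbone must be >= 1, got {n_backbone}")
    types = ("E",) * 4 + ("B",) * n_backbone + ("E",) * 4
    n = len(types)
    bonds = tuple(BondTerm(i, i + 1) for i in range(n - 1))
    angles = tuple(
        AngleTerm(i, i + 1, i + 2, K3_CHAIN)
        for i in range(4, 4 + n_backbone - 2)
    )
    return MoleculeTemplate(f"idp_b{n_backbone}", types, bonds, angles)


def make_linker_lipid_template(sticky_first: bool = False) -> MoleculeTemplate:
    """Minority lipid carrying a 32-bead linker arm on head bead 1.

    The linker is m = 8 four-bead elements alternating inert (L) and sticky
    (S) domains: by default inert-first, i.e. (L4 S4) x 4, placing a spacer
    between the membrane surface and the first sticky domain
    (``sticky_first=True`` flips the alternation).  Linker triples carry the
    chain bending stiffness k3 = 5.
    """
    base = make_lipid_template("minor")
    first, second = ("S", "L") if sticky_first else ("L", "S")
    linker_types = ((first,) * 4 + (second,) * 4) * 4
    types = base.bead_types + linker_types
    bonds = list(base.bonds)
    bonds.append(BondTerm(0, 12))
    bonds += [BondTerm(i, i + 1) for i in range(12, 12 + 31)]
    angles = list(base.angles)
    angles += [AngleTerm(i, i + 1, i + 2, K3_CHAIN) for i in range(12, 12 + 30)]
    return MoleculeTemplate("linker_lipid", types, tuple(bonds), tuple(angles))
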