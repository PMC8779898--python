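"""Observables and morphology classification.

The equilibrium state of a membrane/protein system is summarized by a small
set of scalar observables -- kinetic temperature, minority-lipid domain
metrics, protein condensed/adsorbed fractions, domain circularity -- and a
discrete label over the four corner states of the attraction plane
(eps_EE, eps_EM):

* ``MIXED_DISPERSED``       -- membrane well mixed, proteins dilute;
* ``MIXED_DROPLET``         -- bulk protein droplet, membrane well mixed;
* ``WETTING_DOMAIN``        -- proteins wet a minority-lipid domain as a thin
  layer without bulk condensation;
* ``ADSORBED_DROPLET_DOMAIN`` -- a dense protein droplet adsorbed to a
  minority-lipid domain, protruding into the solvent.

Clustering is contact-based (periodic minimum-image distances, KD-tree) with
cutoffs at or near the interaction range: 1.0 d0 for bead contacts and
1.3 d0 for in-plane headgroup adjacency.  All classifier thresholds default
to 0.5 and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .engine import SystemState
from .model import BEADS

__all__ = [
    "MorphologyReport",
    "kinetic_temperature",
    "contact_clusters",
    "minority_domain_metrics",
    "idp_condensed_fraction",
    "idp_adsorbed_fraction",
    "domain_circularity",
    "classify_morphology",
    "membrane_intact",
    "analyze_state",
    "ObservableRecorder",
]

MIXED_DISPERSED = "MIXED_DISPERSED"
MIXED_DROPLET = "MIXED_DROPLET"
WETTING_DOMAIN = "WETTING_DOMAIN"
ADSORBED_DROPLET_DOMAIN = "ADSORBED_DROPLET_DOMAIN"

_W = BEADS.index("W")
_E = BEADS.index("E")
_HA = BEADS.index("H_A")
_HB = BEADS.index("H_B")
_TA = BEADS.index("T_A")
_TB = BEADS.index("T_B")


def kinetic_temperature(state: SystemState) -> float:
    """Instantaneous kinetic temperature (1/(3N)) sum m |v|^2 (all DOF kept)."""
    return state.kinetic_temperature()


def _safe_wrap(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    p = np.mod(pos, box)
    return np.where(p >= box, 0.0, p)


def contact_clusters(points: np.ndarray, cutoff: float, box: np.ndarray) -> np.ndarray:
    """Connected components of the contact graph (min-image distance < cutoff).

    Returns one integer label per point; an empty input gives an empty
    labeling.  Periodic in every axis of ``box``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    box = np.asarray(box, dtype=np.float64)
    tree = cKDTree(_safe_wrap(points, box), boxsize=box)
    # query strictly-less-than cutoff: shave an epsilon off the closed ball
    pairs = tree.query_pairs(cutoff * (1 - 1e-12), output_type="ndarray")
    if len(pairs) == 0:
        return np.arange(n, dtype=np.int64)
    g = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(g, directed=False)
    return labels.astype(np.int64)


def _circular_mean(x: np.ndarray, L: float) -> float:
    theta = 2.0 * np.pi * x / L
    mx = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    return float((mx * L / (2.0 * np.pi)) % L)


def domain_circularity(points_xy: np.ndarray, box_xy: np.ndarray) -> float:
    """Shape isotropy of an in-plane domain: lambda_min / lambda_max of the
    2D gyration tensor, periodic-aware via circular-mean unwrapping.

    1 means circular/isotropic, 0 collinear (degenerate).
    """
    points_xy = np.asarray(points_xy, dtype=np.float64)
    if len(points_xy) < 3:
        raise ValueError("domain needs at least 3 points")
    box_xy = np.asarray(box_xy, dtype=np.float64)
    d = np.empty_like(points_xy)
    for ax in range(2):
        c = _circular_mean(points_xy[:, ax], box_xy[ax])
        dd = points_xy[:, ax] - c
        d[:, ax] = dd - box_xy[ax] * np.rint(dd / box_xy[ax])
    d -= d.mean(axis=0)
    gyr = d.T @ d / len(d)
    lam = np.linalg.eigvalsh(gyr)
    if lam[1] <= 0:
        return 0.0
    return float(max(lam[0], 0.0) / lam[1])


def minority_domain_metrics(
    state: SystemState, cutoff: float = 1.3
) -> tuple[float, float, float]:
    """(largest-domain fraction, segregation score, largest-domain circularity).

    Minority-lipid head beads are clustered with the in-plane periodic
    distance; the largest-domain fraction counts the distinct minority
    lipids in the biggest cluster over the total.  The segregation score is
    the mean like-type fraction among upper-leaflet headgroup neighbors of
    minority heads, rescaled so ideal mixing (the global minority fraction)
    maps to 0 and a pure like-neighborhood to 1, then clamped to [0, 1].
    Neighbors of a bead's own molecule are excluded.
    """
    box = state.box.array
    is_hb = state.types == _HB
    if not is_hb.any():
        raise ValueError("no minority lipids in the system")
    hb_idx = np.flatnonzero(is_hb)
    hb_mols = state.mol_id[hb_idx]
    mols, inverse = np.unique(hb_mols, return_inverse=True)
    n_minor = len(mols)

    # one in-plane point per lipid: the circular-mean centroid of its head
    # beads (clustering the four head beads individually over-connects the
    # adjacency graph and percolates even at ideal mixing)
    centroids = np.empty((n_minor, 2))
    for m in range(n_minor):
        pts = state.pos[hb_idx[inverse == m]]
        for ax in range(2):
            centroids[m, ax] = _circular_mean(pts[:, ax], box[ax])
    labels = contact_clusters(centroids, cutoff, box[:2])
    counts = np.bincount(labels)
    best_lab = int(np.argmax(counts))
    best = int(counts[best_lab])
    largest_fraction = best / n_minor
    best_cluster = np.flatnonzero(labels == best_lab)
    circ = (
        domain_circularity(centroids[best_cluster], box[:2]) if best >= 3 else 0.0
    )

    # segregation score against the ideal-mixing null
    upper_heads = np.flatnonzero(
        ((state.types == _HA) | (state.types == _HB)) & (state.leaflet == 1)
    )
    if len(upper_heads) == 0:
        return largest_fraction, 0.0, circ
    head_xy = _safe_wrap(state.pos[upper_heads][:, :2], box[:2])
    tree = cKDTree(head_xy, boxsize=box[:2])
    head_types = state.types[upper_heads]
    head_mols = state.mol_id[upper_heads]
    minority_mask = head_types == _HB
    p0 = minority_mask.mean()
    if p0 >= 1.0:
        return largest_fraction, 0.0, circ
    like_fracs = []
    centers = np.flatnonzero(minority_mask)
    neighbor_lists = tree.query_ball_point(head_xy[centers], cutoff * (1 - 1e-12))
    for c, nbrs in zip(centers, neighbor_lists):
        nbrs = [b for b in nbrs if head_mols[b] != head_mols[c]]
        if not nbrs:
            continue
        like_fracs.append(minority_mask[nbrs].mean())
    if not like_fracs:
        return largest_fraction, 0.0, circ
    score = (float(np.mean(like_fracs)) - p0) / (1.0 - p0)
    return largest_fraction, float(np.clip(score, 0.0, 1.0)), circ


def _idp_mols(state: SystemState) -> np.ndarray:
    return np.unique(state.mol_id[state.types == _E])


def idp_condensed_fraction(
    state: SystemState, min_size: int = 10, cutoff: float = 0.6
) -> float:
    """Fraction of proteins belonging to endcap-association clusters of at
    least ``min_size`` molecules.

    Two proteins are linked when any of their endcap (E) beads lie within
    ``cutoff``; linkage is transitive, so a bulk droplet counts as one
    cluster however large.  The association distance (default 0.6 d0) sits
    well inside the soft-repulsion core: endcaps of *attractive* pairs
    (eps_EE ~ 0.7) overlap to r ~ 0.3-0.5, while neutral endcaps crowded by
    solvent pressure remain at r ~ 0.8-1.0, so this cutoff separates true
    association from incidental proximity; at the interaction range (1.0)
    the contact graph percolates even for an ideal dispersed phase at the
    concentrations simulated here.
    """
    e_idx = np.flatnonzero(state.types == _E)
    if len(e_idx) == 0:
        raise ValueError("no proteins in the system")
    labels = contact_clusters(state.pos[e_idx], cutoff, state.box.array)
    mols = state.mol_id[e_idx]
    # merge bead-contact components that share a molecule (two endcaps)
    parent = np.arange(labels.max() + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in np.unique(mols):
        labs = np.unique(labels[mols == m])
        r = find(labs[0])
        for lab in labs[1:]:
            parent[find(lab)] = r
    roots = np.array([find(l) for l in labels])
    total = len(np.unique(mols))
    condensed = 0
    for r in np.unique(roots):
        cluster_mols = np.unique(mols[roots == r])
        if len(cluster_mols) >= min_size:
            condensed += len(cluster_mols)
    return condensed / total


def idp_adsorbed_fraction(state: SystemState, cutoff: float = 1.0) -> float:
    """Fraction of proteins with at least one endcap bead within ``cutoff``
    of any lipid headgroup bead."""
    e_idx = np.flatnonzero(state.types == _E)
    if len(e_idx) == 0:
        raise ValueError("no proteins in the system")
    heads = np.flatnonzero((state.types == _HA) | (state.types == _HB))
    if len(heads) == 0:
        raise ValueError("no membrane in the system")
    box = state.box.array
    tree = cKDTree(_safe_wrap(state.pos[heads], box), boxsize=box)
    d, _ = tree.query(_safe_wrap(state.pos[e_idx], box), k=1)
    touching_mols = np.unique(state.mol_id[e_idx[d < cutoff]])
    return len(touching_mols) / len(_idp_mols(state))


def idp_protrusion(state: SystemState) -> float:
    """90th-percentile height of endcap beads above the upper headgroup plane.

    Distinguishes a thin wetting layer (~<= 2 d0) from a droplet protruding
    into the solvent; reported for inspection, not used by the classifier.
    """
    e_idx = np.flatnonzero(state.types == _E)
    heads = np.flatnonzero(
        ((state.types == _HA) | (state.types == _HB)) & (state.leaflet == 1)
    )
    if len(e_idx) == 0 or len(heads) == 0:
        return float("nan")
    Lz = state.box.lengths[2]
    z_head = _circular_mean(state.pos[heads][:, 2], Lz)
    dz = state.pos[e_idx][:, 2] - z_head
    dz -= Lz * np.rint(dz / Lz)
    return float(np.percentile(dz, 90))


def classify_morphology(
    largest_domain_fraction: float | None,
    condensed_fraction: float | None,
    adsorbed_fraction: float | None,
    theta_dom: float = 0.5,
    theta_cond: float = 0.5,
    theta_ads: float = 0.5,
) -> str:
    """Quadrant classifier over the membrane and protein order parameters.

    Membrane axis: DOMAIN when the largest minority domain holds at least
    ``theta_dom`` of the minority lipids.  Protein axis: CONDENSED when the
    condensed fraction reaches ``theta_cond``; otherwise WETTING when the
    adsorbed fraction reaches ``theta_ads``, else DISPERSED.  Missing axes
    (no membrane / no proteins) yield a PARTIAL_* sentinel label.
    """
    if condensed_fraction is None or adsorbed_fraction is None:
        if largest_domain_fraction is None:
            return "PARTIAL_UNKNOWN"
        return (
            "PARTIAL_DOMAIN" if largest_domain_fraction >= theta_dom else "PARTIAL_MIXED"
        )
    condensed = condensed_fraction >= theta_cond
    if largest_domain_fraction is None:
        return "PARTIAL_DROPLET" if condensed else "PARTIAL_DISPERSED"
    domain = largest_domain_fraction >= theta_dom
    wetting = (not condensed) and adsorbed_fraction >= theta_ads
    if domain:
        return ADSORBED_DROPLET_DOMAIN if condensed else WETTING_DOMAIN
    if condensed:
        return MIXED_DROPLET
    if wetting:
        # adsorbed without a consolidated domain: still a wetting morphology
        return WETTING_DOMAIN
    return MIXED_DISPERSED


def membrane_intact(state: SystemState) -> bool:
    """Sanity gate: solvent excluded from the hydrophobic slab and both
    leaflets' headgroups still on their initial sides (on average)."""
    tails = np.flatnonzero((state.types == _TA) | (state.types == _TB))
    if len(tails) == 0:
        return False
    Lz = state.box.lengths[2]
    z_mid = _circular_mean(state.pos[tails][:, 2], Lz)

    def rel_z(idx):
        dz = state.pos[idx][:, 2] - z_mid
        return dz - Lz * np.rint(dz / Lz)

    w_idx = np.flatnonzero(state.types == _W)
    if len(w_idx):
        inside = np.abs(rel_z(w_idx)) < 1.5
        if inside.mean() >= 0.01:
            return False
    heads = (state.types == _HA) | (state.types == _HB)
    for side in (1, -1):
        idx = np.flatnonzero(heads & (state.leaflet == side))
        if len(idx) and not (rel_z(idx).mean() * side > 0):
            return False
    return True


@dataclass
class MorphologyReport:
    """Scalar observables plus the discrete morphology label."""

    temperature: float
    density: float
    largest_domain_fraction: float | None = None
    segregation: float | None = None
    condensed_fraction: float | None = None
    adsorbed_fraction: float | None = None
    circularity: float | None = None
    protrusion: float | None = None
    label: str = "PARTIAL_UNKNOWN"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def __str__(self) -> str:
        lines = [f"{k:>24s} : {v}" for k, v in self.to_dict().items()]
        return "\n".join(lines)


def analyze_state(
    state: SystemState,
    min_size: int = 10,
    theta_dom: float = 0.5,
    theta_cond: float = 0.5,
    theta_ads: float = 0.5,
) -> MorphologyReport:
    """Compute every applicable observable and classify the morphology."""
    has_mem = bool(((state.types == _HB) | (state.types == _HA)).any())
    has_minor = bool((state.types == _HB).any())
    has_idp = bool((state.types == _E).any())
    dom = seg = circ = None
    if has_minor:
        dom, seg, circ = minority_domain_metrics(state)
    cond = ads = prot = None
    if has_idp:
        cond = idp_condensed_fraction(state, min_size=min_size)
        if has_mem:
            ads = idp_adsorbed_fraction(state)
            prot = idp_protrusion(state)
    label = classify_morphology(dom, cond, ads, theta_dom, theta_cond, theta_ads)
    return MorphologyReport(
        temperature=kinetic_temperature(state) if state.n else 0.0,
        density=state.n / state.box.volume,
        largest_domain_fraction=dom,
        segregation=seg,
        condensed_fraction=cond,
        adsorbed_fraction=ads,
        circularity=circ,
        protrusion=prot,
        label=label,
    )


def average_reports(reports: list[MorphologyReport], **thresholds) -> MorphologyReport:
    """Mean of the scalar fields over frames, re-classified from the means."""
    if not reports:
        raise ValueError("no reports to average")

    def mean(attr):
        vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    dom, cond, ads = mean("largest_domain_fraction"), mean("condensed_fraction"), mean("adsorbed_fraction")
    return MorphologyReport(
        temperature=mean("temperature") or 0.0,
        density=mean("density") or 0.0,
        largest_domain_fraction=dom,
        segregation=mean("segregation"),
        condensed_fraction=cond,
        adsorbed_fraction=ads,
        circularity=mean("circularity"),
        protrusion=mean("protrusion"),
        label=classify_morphology(dom, cond, ads, **thresholds),
    )


class ObservableRecorder:
    """Engine observer collecting a per-interval observable time series.

    Records step, kinetic temperature, momentum components and (optionally)
    the morphology metrics; exports to a pandas DataFrame / CSV.
    """

    def __init__(self, morphology: bool = False, min_size: int = 10) -> None:
        self.rows: list[dict] = []
        self.morphology = morphology
        self.min_size = min_size

    def __call__(self, state: SystemState) -> None:
        p = state.total_momentum()
        row = {
            "step": state.step,
            "temperature": kinetic_temperature(state),
            "px": p[0],
            "py": p[1],
            "pz": p[2],
        }
        if self.morphology:
            rep = analyze_state(state, min_size=self.min_size)
            row.update(
                {
                    k: v
                    for k, v in rep.to_dict().items()
                    if k not in ("temperature", "label")
                }
            )
            row["label"] = rep.label
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)
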