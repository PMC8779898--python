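"""Observables: clustering, domain metrics, protein fractions, circularity,
the quadrant classifier and the membrane sanity gate."""

import numpy as np
import pytest

from dpdmem.analysis import (
    ADSORBED_DROPLET_DOMAIN,
    MIXED_DISPERSED,
    MIXED_DROPLET,
    WETTING_DOMAIN,
    classify_morphology,
    contact_clusters,
    domain_circularity,
    idp_adsorbed_fraction,
    idp_condensed_fraction,
    kinetic_temperature,
    membrane_intact,
    minority_domain_metrics,
    analyze_state,
)
from dpdmem.builder import make_fixture
from dpdmem.engine import SimulationBox, SystemState
from dpdmem.model import BEADS

_W = BEADS.index("W")
_E = BEADS.index("E")
_HA = BEADS.index("H_A")
_HB = BEADS.index("H_B")
_TA = BEADS.index("T_A")


def brute_force_components(points, cutoff, box):
    n = len(points)
    L = np.asarray(box)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            d = points[i] - points[j]
            d -= L * np.rint(d / L)
            if (d**2).sum() < cutoff * cutoff:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


class TestContactClusters:
    def test_far_beads_separate(self):
        pts = np.array([[1.0, 1.0, 1.0], [2.5, 1.0, 1.0]])
        labels = contact_clusters(pts, 1.0, np.array([8.0, 8.0, 8.0]))
        assert labels[0] != labels[1]

    def test_chain_connects(self):
        pts = np.array([[1 + 0.5 * i, 1.0, 1.0] for i in range(8)])
        labels = contact_clusters(pts, 1.0, np.array([16.0, 16.0, 16.0]))
        assert len(np.unique(labels)) == 1

    def test_periodic_wraparound_connects(self):
        pts = np.array([[0.1, 1.0, 1.0], [7.9, 1.0, 1.0]])
        labels = contact_clusters(pts, 1.0, np.array([8.0, 8.0, 8.0]))
        assert labels[0] == labels[1]

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_union_find_oracle(self, trial):
        rng = np.random.default_rng(7000 + trial)
        n = int(rng.integers(30, 300))
        box = np.array([6.0, 6.0, 6.0])
        pts = rng.uniform(0, 6.0, (n, 3))
        got = contact_clusters(pts, 1.0, box)
        expected = brute_force_components(pts, 1.0, box)
        # same partition (labels may differ)
        for a in range(n):
            for b in range(a + 1, min(a + 40, n)):
                assert (got[a] == got[b]) == (expected[a] == expected[b])

    def test_empty_input(self):
        assert len(contact_clusters(np.zeros((0, 3)), 1.0, np.array([5.0, 5.0, 5.0]))) == 0


class TestCircularity:
    def test_circle_isotropic(self):
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = 10.0 + 2.0 * np.c_[np.cos(theta), np.sin(theta)]
        c = domain_circularity(pts, np.array([40.0, 40.0]))
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_line_degenerate(self):
        pts = np.c_[np.linspace(5, 9, 20), np.full(20, 7.0)]
        assert domain_circularity(pts, np.array([40.0, 40.0])) == pytest.approx(0.0, abs=1e-12)

    def test_two_to_one_ellipse(self):
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = 15.0 + np.c_[4.0 * np.cos(theta), 2.0 * np.sin(theta)]
        # eigenvalue ratio equals the squared axis ratio
        assert domain_circularity(pts, np.array([40.0, 40.0])) == pytest.approx(0.25, abs=1e-9)

    def test_wraps_across_boundary(self):
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.c_[np.cos(theta), np.sin(theta)] * 2.0  # centered on the origin corner
        pts %= 20.0
        assert domain_circularity(pts, np.array([20.0, 20.0])) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            domain_circularity(np.zeros((2, 2)), np.array([10.0, 10.0]))


def _membrane_state(minor_xy, major_xy, box=(12.0, 12.0, 16.0)):
    """Synthetic flat 'membrane' of single-bead headgroup markers per lipid.

    Each lipid is represented by one H bead in the upper leaflet (enough for
    the in-plane domain metrics, which cluster per-lipid head centroids).
    """
    box = SimulationBox(box)
    z = box.lengths[2] / 2 + 2.0
    pts, types = [], []
    for x, y in minor_xy:
        pts.append([x, y, z])
        types.append(_HB)
    for x, y in major_xy:
        pts.append([x, y, z])
        types.append(_HA)
    n = len(pts)
    state = SystemState(box, np.array(pts), types=np.array(types, dtype=np.int64))
    state.leaflet = np.ones(n, dtype=np.int8)
    state.mol_id = np.arange(n, dtype=np.int64)
    return state


class TestMinorityDomainMetrics:
    def test_single_patch_owns_all(self):
        minor = [(5 + 0.9 * i, 5 + 0.9 * j) for i in range(3) for j in range(3)]
        major = [(1 + i, 1.0) for i in range(8)]
        frac, seg, _ = minority_domain_metrics(_membrane_state(minor, major))
        assert frac == 1.0
        assert seg > 0.5

    def test_two_equal_patches(self):
        patch = [(0.9 * i, 0.9 * j) for i in range(2) for j in range(3)]
        minor = [(1 + x, 1 + y) for x, y in patch] + [(7 + x, 7 + y) for x, y in patch]
        frac, _, _ = minority_domain_metrics(_membrane_state(minor, [(4.0, 11.0)]))
        assert frac == pytest.approx(0.5)

    def test_random_mixing_scores_near_zero(self):
        # 200 random placements at 16% minority: mean segregation consistent
        # with the ideal-mixing null (within two standard errors of zero)
        rng = np.random.default_rng(42)
        lattice = np.array(
            [(0.5 + 1.15 * i, 0.5 + 1.15 * j) for i in range(10) for j in range(10)]
        )
        scores = []
        for _ in range(200):
            chosen = rng.choice(100, size=16, replace=False)
            mask = np.zeros(100, dtype=bool)
            mask[chosen] = True
            st = _membrane_state(lattice[mask], lattice[~mask])
            _, seg, _ = minority_domain_metrics(st)
            scores.append(seg)
        scores = np.asarray(scores)
        se = scores.std() / np.sqrt(len(scores))
        # clamping at zero makes the mean slightly positive under the null
        assert scores.mean() < max(0.05, 2 * se + 0.02)

    def test_requires_minority(self):
        with pytest.raises(ValueError):
            minority_domain_metrics(make_fixture("pure-water-8"))


def _idp_cloud(cluster_sizes, spacing=5.0):
    """Synthetic endcap-only 'proteins': 2 E beads each, clusters separated."""
    box = SimulationBox((40.0, 40.0, 40.0))
    pos, mols = [], []
    mol = 0
    for ci, size in enumerate(cluster_sizes):
        cx = 3.0 + ci * spacing * 2
        for k in range(size):
            base = np.array([cx + 0.25 * k, 3.0, 3.0])
            pos += [base, base + [0.0, 0.3, 0.0]]
            mols += [mol, mol]
            mol += 1
    n = len(pos)
    state = SystemState(box, np.array(pos), types=np.full(n, _E, dtype=np.int64))
    state.mol_id = np.array(mols, dtype=np.int64)
    return state


class TestIdpFractions:
    def test_all_isolated_zero(self):
        state = _idp_cloud([1] * 12)
        assert idp_condensed_fraction(state, min_size=10) == 0.0

    def test_single_aggregate_full(self):
        state = _idp_cloud([12])
        assert idp_condensed_fraction(state, min_size=10) == 1.0

    def test_two_cluster_fixture_fraction(self):
        # 12 + 3 proteins, min_size 10: only the large cluster counts
        state = _idp_cloud([12, 3])
        assert idp_condensed_fraction(state, min_size=10) == pytest.approx(12 / 15)

    def test_adsorbed_half(self):
        box = SimulationBox((20.0, 20.0, 20.0))
        pos, types, mols = [], [], []
        for i in range(10):
            pos.append([2.0 + i, 5.0, 10.0])
            types.append(_HA)
            mols.append(i)
        for k in range(10):
            z = 10.5 if k < 5 else 16.0  # five touching, five far away
            pos.append([2.0 + k, 5.0, z])
            types.append(_E)
            mols.append(100 + k)
        state = SystemState(
            box, np.array(pos), types=np.array(types, dtype=np.int64),
            mol_id=np.array(mols, dtype=np.int64),
        )
        assert idp_adsorbed_fraction(state) == pytest.approx(0.5)


class TestClassifier:
    @pytest.mark.parametrize(
        "dom,cond,ads,expected",
        [
            (0.9, 0.9, 0.9, ADSORBED_DROPLET_DOMAIN),
            (0.1, 0.05, 0.02, MIXED_DISPERSED),
            (0.1, 0.9, 0.05, MIXED_DROPLET),
            (0.9, 0.1, 0.9, WETTING_DOMAIN),
            (0.2, 0.1, 0.8, WETTING_DOMAIN),  # adsorbed but domain not consolidated
        ],
    )
    def test_quadrants(self, dom, cond, ads, expected):
        assert classify_morphology(dom, cond, ads) == expected

    def test_partial_labels(self):
        assert classify_morphology(0.9, None, None) == "PARTIAL_DOMAIN"
        assert classify_morphology(None, 0.9, 0.0) == "PARTIAL_DROPLET"
        assert classify_morphology(None, None, None) == "PARTIAL_UNKNOWN"

    def test_analyze_state_pure_water(self):
        rep = analyze_state(make_fixture("pure-water-8", seed=1))
        assert rep.label == "PARTIAL_UNKNOWN"
        assert rep.density == pytest.approx(3.0)
        assert rep.temperature == pytest.approx(1.0, abs=1e-9)


class TestMembraneIntact:
    def test_fresh_membrane_true(self):
        assert membrane_intact(make_fixture("mini-membrane-12x12x16", seed=1))

    def test_solvent_flooded_false(self):
        state = make_fixture("mini-membrane-12x12x16", seed=1)
        w = state.types == _W
        # teleport the solvent into the hydrophobic slab
        state.pos[w, 2] = 8.0
        assert not membrane_intact(state)

    def test_no_membrane_false(self):
        assert not membrane_intact(make_fixture("pure-water-8"))


def test_kinetic_temperature_zero_velocities():
    state = make_fixture("two-bead-dimer")
    assert kinetic_temperature(state) == 0.0
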