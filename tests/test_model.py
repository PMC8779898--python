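"""Force-field constants, the epsilon mapping and molecule topologies."""

import math

import numpy as np
import pytest

from dpdmem.model import (
    A_SS,
    A_WE,
    BEAD_TYPES,
    BEADS,
    AngleTerm,
    BondTerm,
    EpsilonSpec,
    InteractionTable,
    MoleculeTemplate,
    a_to_epsilon,
    epsilon_to_a,
    make_idp_template,
    make_linker_lipid_template,
    make_lipid_template,
    sigma_from_gamma,
)


class TestEpsilonMapping:
    @pytest.mark.parametrize(
        "a,baseline,expected",
        [
            (8.0, 25.0, 0.68),
            (25.0, 25.0, 0.0),
            (5.0, 30.0, 25.0 / 30.0),
            (5.0, 25.0, 0.8),
        ],
    )
    def test_a_to_epsilon(self, a, baseline, expected):
        assert a_to_epsilon(a, baseline) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "eps,baseline,expected",
        [(0.8, 25.0, 5.0), (0.0, 30.0, 30.0), (0.68, 25.0, 8.0)],
    )
    def test_epsilon_to_a(self, eps, baseline, expected):
        assert epsilon_to_a(eps, baseline) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 0.25, 0.68, 0.8, 1.0])
    @pytest.mark.parametrize("baseline", [A_WE, A_SS])
    def test_round_trip_identity(self, eps, baseline):
        assert a_to_epsilon(epsilon_to_a(eps, baseline), baseline) == pytest.approx(
            eps, abs=1e-12
        )

    def test_negative_epsilon_for_super_baseline_repulsion(self):
        # values above the solvent baseline are allowed and map to eps < 0
        assert a_to_epsilon(30.0, 25.0) == pytest.approx(-0.2)

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            a_to_epsilon(8.0, 0.0)
        with pytest.raises(ValueError):
            epsilon_to_a(0.5, -1.0)


class TestSigmaFromGamma:
    @pytest.mark.parametrize(
        "gamma,kBT,expected",
        [(4.5, 1.0, 3.0), (0.0, 1.0, 0.0), (2.0, 2.0, math.sqrt(8.0))],
    )
    def test_fluctuation_dissipation(self, gamma, kBT, expected):
        assert sigma_from_gamma(gamma, kBT) == pytest.approx(expected, abs=1e-12)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            sigma_from_gamma(-1.0)


class TestInteractionTable:
    def test_fixed_entries(self, neutral_table):
        a = neutral_table.a
        idx = BEADS.index
        assert a[idx("W"), idx("W")] == 25
        assert a[idx("W"), idx("B")] == 23
        assert a[idx("W"), idx("T_A")] == 75
        assert a[idx("T_A"), idx("T_A")] == 10
        assert a[idx("H_A"), idx("H_A")] == 30
        assert a[idx("L"), idx("S")] == 30
        # neutral defaults for the variable entries
        assert a[idx("E"), idx("E")] == 25
        assert a[idx("E"), idx("H_B")] == 25
        assert a[idx("E"), idx("S")] == 30

    def test_symmetric_and_valid(self, neutral_table):
        assert np.array_equal(neutral_table.a, neutral_table.a.T)
        assert np.array_equal(neutral_table.gamma, neutral_table.gamma.T)
        assert (neutral_table.gamma == 4.5).all()
        neutral_table.validate()

    def test_sigma_matrix(self, neutral_table):
        assert neutral_table.sigma[0, 0] == pytest.approx(3.0)

    def test_only_variable_entries_settable(self, neutral_table):
        neutral_table.set_a(("E", "E"), 8.0)
        assert neutral_table.a[BEADS.index("E"), BEADS.index("E")] == 8.0
        assert neutral_table.a[BEADS.index("E"), BEADS.index("E")] == neutral_table.a.T[1, 1]
        with pytest.raises(ValueError):
            neutral_table.set_a(("W", "W"), 10.0)
        with pytest.raises(ValueError):
            neutral_table.set_a(("E", "E"), -1.0)

    def test_epsilon_round_trip_through_table(self, neutral_table):
        neutral_table.set_epsilon(("E", "H_B"), 0.8)
        assert neutral_table.a[BEADS.index("E"), BEADS.index("H_B")] == pytest.approx(5.0)
        assert neutral_table.get_epsilon(("E", "H_B")) == pytest.approx(0.8)

    def test_epsilon_spec_builds_table(self):
        t = EpsilonSpec(eps_ee=0.68, eps_em=0.8, eps_es=0.83).make_table()
        idx = BEADS.index
        assert t.a[idx("E"), idx("E")] == pytest.approx(8.0)
        assert t.a[idx("E"), idx("H_B")] == pytest.approx(5.0)
        assert t.a[idx("E"), idx("S")] == pytest.approx(30 * 0.17)


class TestTemplates:
    @pytest.mark.parametrize("species,h,t", [("major", "H_A", "T_A"), ("minor", "H_B", "T_B")])
    def test_lipid_topology(self, species, h, t):
        tmpl = make_lipid_template(species)
        assert tmpl.n_beads == 12
        assert len(tmpl.bonds) == 11
        assert tmpl.is_tree()
        assert tmpl.bead_types == (h,) * 4 + (t,) * 8
        assert all(b.k == 128.0 and b.l0 == 0.5 for b in tmpl.bonds)
        # stiff tails: one junction triple + two all-tail triples per tail
        assert len(tmpl.angles) == 6
        assert all(a.k3 == 15.0 and a.phi0 == 0.0 for a in tmpl.angles)

    def test_lipid_without_junction_angles(self):
        tmpl = make_lipid_template("major", include_junction_angles=False)
        assert len(tmpl.angles) == 4

    @pytest.mark.parametrize(
        "n,beads,angles", [(6, 14, 4), (16, 24, 14), (8, 16, 6), (1, 9, 0)]
    )
    def test_idp_topology(self, n, beads, angles):
        tmpl = make_idp_template(n)
        assert tmpl.n_beads == beads
        assert len(tmpl.bonds) == beads - 1
        assert tmpl.is_tree()
        assert len(tmpl.angles) == angles
        assert all(a.k3 == 5.0 for a in tmpl.angles)
        assert tmpl.bead_types[:4] == ("E",) * 4
        assert tmpl.bead_types[-4:] == ("E",) * 4
        assert tmpl.bead_types[4:-4] == ("B",) * n

    def test_idp_requires_backbone(self):
        with pytest.raises(ValueError):
            make_idp_template(0)

    def test_linker_lipid_topology(self):
        tmpl = make_linker_lipid_template()
        assert tmpl.n_beads == 44
        assert len(tmpl.bonds) == 43
        assert tmpl.is_tree()
        counts = {t: tmpl.bead_types.count(t) for t in set(tmpl.bead_types)}
        assert counts["L"] == 16 and counts["S"] == 16
        assert counts["H_B"] == 4 and counts["T_B"] == 8
        # inert-first: a spacer between the membrane surface and first sticky block
        assert tmpl.bead_types[12:16] == ("L",) * 4
        assert tmpl.bead_types[16:20] == ("S",) * 4
        sticky = make_linker_lipid_template(sticky_first=True)
        assert sticky.bead_types[12:16] == ("S",) * 4

    def test_angles_span_bonded_triples(self):
        # the template validator rejects angles not backed by two bonds
        with pytest.raises(ValueError):
            MoleculeTemplate(
                "bad",
                ("W", "W", "W"),
                bonds=(BondTerm(0, 1),),
                angles=(AngleTerm(0, 1, 2, 5.0),),
            )

    def test_serialization_round_trip(self):
        tmpl = make_linker_lipid_template()
        back = MoleculeTemplate.from_dict(tmpl.to_dict())
        assert back.bead_types == tmpl.bead_types
        assert back.bonds == tmpl.bonds
        assert back.angles == tmpl.angles

    def test_bead_type_table_stable(self):
        assert BEAD_TYPES == ("W", "E", "B", "H_A", "T_A", "H_B", "T_B", "L", "S")
        assert len({BEADS.index(t) for t in BEAD_TYPES}) == 9
        with pytest.raises(KeyError):
            BEADS.index("X")
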