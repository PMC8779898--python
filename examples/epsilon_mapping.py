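"""Force-field anchors: the dimensionless attraction scale.

Attractions between the protein endcaps (E) and their partners are quoted as
eps = (baseline - a) / baseline, with the water/endcap repulsion a_WE = 25 as
baseline for E-E and E-headgroup pairs, and the sticky-sticky repulsion
a_SS = 30 for the E-sticky pair.  eps = 0 means "interacts like solvent",
eps = 1 maximal attraction.
"""

from dpdmem.model import A_SS, A_WE, BEADS, EpsilonSpec, a_to_epsilon, epsilon_to_a

print("endcap self-attraction for a_EE=8   :", a_to_epsilon(8.0, A_WE))
print("endcap-headgroup attraction, a_EM=5 :", a_to_epsilon(5.0, A_WE))
print("endcap-sticky attraction for a_ES=5 :", round(a_to_epsilon(5.0, A_SS), 2))
print("a value realizing eps=0.8 at a_WE   :", epsilon_to_a(0.8, A_WE))

table = EpsilonSpec(eps_ee=0.68, eps_em=0.8).make_table()
i, j = BEADS.index("E"), BEADS.index("H_B")
print("\neffective conservative matrix entries (kBT/d0):")
print("  a_EE  =", table.a[i, i], " (strongly self-attracting endcaps)")
print("  a_EM  =", table.a[i, j], " (endcaps bind minority headgroups)")
print("  a_WW  =", table.a[0, 0], " (solvent baseline, fixed)")
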