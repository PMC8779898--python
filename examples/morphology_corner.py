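"""One corner of the morphology diagram, scaled down.

Runs the wetting corner (eps_EE = 0, eps_EM = 0.8): proteins with no
self-attraction but a strong attraction to the minority lipid headgroups
should wet the membrane and drag the minority lipids into a single domain,
without forming a bulk droplet.  Takes about a minute.
"""

from dpdmem import study

report = study.run_corner(eps_ee=0.0, eps_em=0.8, seed=1)

print("scaled-down system: 8x8x14 box, 96 lipids (16 minority), 16 B6 proteins")
print(report)
print()
print("Interpretation: a large adsorbed fraction with a sub-threshold")
print("condensed fraction and a majority-of-minority domain is the")
print(f"'{report.label}' state: a thin protein layer wetting a lipid domain.")
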