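# Methods

## The physical model

`dpdmem` simulates a dilute phase of self-associating, intrinsically
disordered proteins (IDPs) near a two-component lipid bilayer with
dissipative particle dynamics (DPD), a coarse-grained, explicit-solvent,
momentum-conserving particle method.  All quantities are in reduced units:
lengths in the interaction cutoff d0 (≈ 1 nm), energies in kBT, bead mass
m = 1, time in τ = √(m d0²/kBT).

Beads interact through three short-ranged non-bonded forces, all vanishing
beyond r = d0 = 1:

* conservative soft repulsion  F^C = a_ij (1 − r) r̂,
* dissipative drag             F^D = −γ (1 − r)² (r̂·v_ij) r̂,
* random kicks                 F^R = σ (1 − r) ζ_ij r̂ / √Δt,

with σ² = 2 γ kBT (fluctuation–dissipation), γ = 4.5 for all pairs and ζ_ij
a symmetric, zero-mean, unit-variance variate drawn per pair per step.  The
dissipative + random pair forces act as a Galilean-invariant thermostat
that preserves hydrodynamics.

Nine bead types define the chemistry: solvent W; IDP endcap E and backbone
B; majority-lipid head/tail H_A/T_A; minority head/tail H_B/T_B; linker
inert/sticky L/S.  The conservative matrix is fixed except for three
entries — a_EE, a_EM (≡ a_{E,H_B}) and a_ES — which are the control
parameters of the study.  Attractions are quoted as the dimensionless

    ε = (a_baseline − a) / a_baseline,

with baseline a_WE = 25 for the endcap pairs and a_SS = 30 for the
endcap–sticky pair, so ε = 0 is "no net attraction relative to solvent"
and ε = 1 maximal attraction.  ε may formally be negative (a above the
baseline); nothing is clamped, but only 0 ≤ ε ≤ 1 is explored.

Molecules are Hookean-bonded bead chains (k = 128 kBT/d0², l0 = 0.5 d0)
with a bending potential U = k₃(1 − cos(φ − φ0)) on selected consecutive
triples, φ measured between successive bond vectors and φ0 = 0 throughout:

* **lipids** (12 beads): a linear 4-bead head chain with two 4-bead tails
  attached to the last two head beads; k₃ = 15 on the tail triples
  including, by default, the head–tail junction triple (this gives the
  tails a defined orientation; `include_junction_angles=False` restricts
  bending to all-tail triples).  The two species are structurally and
  energetically identical — only their interaction with the IDPs differs.
* **IDPs** (telechelic polymers, 8 + n beads): four E beads, n backbone B
  beads (B6, B8, B16 …), four E beads; k₃ = 5 on all-backbone triples.
* **linker–lipids** (44 beads): a minority lipid with a 32-bead arm on the
  first head bead, m = 8 four-bead elements alternating inert-first
  (L₄S₄)×4; k₃ = 5 on all-linker triples.  Inert-first placement puts a
  spacer between the membrane surface and the first sticky block;
  `sticky_first=True` flips the alternation.

## Integration

The modified velocity-Verlet scheme of the DPD literature:

1. r ← r + Δt v + ½Δt² f;   ṽ = v + λ Δt f
2. f′ = F(r, ṽ)   (dissipative force uses the predicted velocity ṽ)
3. v ← v + ½Δt (f + f′)

with Δt = 0.02 τ and λ = 0.5 (configurable; the λ = ½ choice recovers
standard velocity-Verlet structure).  Positions are wrapped into [0, L)
per axis; all distances use the minimum-image convention.  At Δt = 0.02
the integrator's known small temperature bias is below 1% (the acceptance
run measures ⟨T⟩ ≈ 1.007).

Randomness is a counter-based hash RNG keyed on (min(i,j), max(i,j), step,
seed) returning uniform variates on [−√3, √3] (unit variance; uniform
variates are standard in DPD and cheaper than Gaussians).  This makes
trajectories bitwise reproducible, independent of evaluation order, and
lets both backends draw identical noise without sharing generator state.

Degenerate inputs: exactly overlapping beads (r = 0) contribute no pair
force (the soft potential is finite there, the direction undefined, and
the event has measure zero); a fully collapsed bond is nudged along x by
machine epsilon; cos φ is clamped to [−1, 1] and the anti-collinear angle
returns the zero-force limit.

## Backends

The **reference engine** is a single-array integrator with a cell-list
neighbor search (cells of edge ≥ d0, 13 half-shell neighbor offsets,
counting-sort bucketing; non-integer box edges widen the cells to
L/⌊L⌋).

The **cell-graph backend** emulates an event-triggered, two-phase
message-passing decomposition: one logical vertex per unit-volume cell
(≈ 3–4 resident beads at density 3), edges to its 26 periodic neighbors.
Each step runs a force phase (Share broadcasts of resident beads;
non-bonded and Hookean terms computed on receipt; angle terms computed by
the vertex owning the middle bead once both ends are received, with
AngleForce messages to the end-bead owners) and a movement phase (local
integration, BeadExit/BeadEntrance residency handoff).  Execution is
sequential-deterministic with phases as barriers: the contract under test
is the message protocol and its locality, not hardware concurrency.
Double-counting is avoided by assigning each pair to the vertex owning its
lower-numbered bead; a bonded partner beyond one cell shell is a hard
error (a bond at k = 128, l0 = 0.5 never legitimately stretches past 1 d0
in a stable run), as is a bead moving more than one cell per step.

Both backends call the same per-pair kernels and the same pair RNG.  In
strict-order mode (default for comparisons) non-bonded contributions are
accumulated in canonical (i, j) order, so the two backends produce
**bitwise-identical** trajectories from the same seed; the fast
enumeration-order path differs only in floating-point summation order.

## System construction

Bilayers are pre-assembled flat at the box midplane, normal along z: equal
lipid counts per leaflet (avoiding built-in spontaneous curvature), all
minority lipids on uniformly random lattice sites of the **upper** leaflet
only, heads toward the solvent, tails toward the midplane.  The in-plane
lattice is a snug ⌈√count⌉-type grid with ±0.1 d0 jitter to break
symmetry; a configuration error reports the minimal cross-section when
lipids would be packed below ~0.5 d0² each.  IDPs insert as slightly
perturbed straight rods at random positions/orientations, rejected if any
bead falls within the slab |z − L_z/2| < 4·l0 = 2 d0 (the approximate
bilayer half-thickness at rest bond length).  Solvent beads fill the
remaining space by rejection sampling against the same slab until the
global bead count is round(ρV) with ρ = 3 d0⁻³ — soft potentials tolerate
the residual overlaps, which anneal within a short equilibration.
Velocities are Maxwell–Boltzmann with the net momentum subtracted exactly
and the kinetic temperature rescaled exactly to kBT = 1.  Builds are
deterministic given the recipe seed.

## Observables and classification

* **Kinetic temperature**: (1/3N) Σ m|v|²; no constraint degrees of
  freedom are removed (there are none — all bonds are springs).
* **Contact clusters**: connected components of the graph with edges
  between beads closer than a cutoff (periodic KD-tree), default cutoff
  1.0 d0.
* **Minority domain metrics**: one in-plane point per minority lipid (the
  circular-mean centroid of its H_B head beads), clustered at 1.3 d0.
  The largest-domain fraction is the share of minority lipids in the
  biggest cluster.  Clustering the four head beads individually
  over-connects the adjacency graph and percolates even at ideal mixing
  (measured largest-cluster fractions of 0.7–0.9 for randomly mixed
  membranes), which would erase the mixed/domain distinction; per-lipid
  centroids keep the mixed state sub-critical while a close-packed domain
  still reads as one cluster.
* **Segregation score**: mean like-type fraction among upper-leaflet
  headgroup neighbors (in-plane, 1.3 d0, own molecule excluded) of
  minority heads, affinely rescaled so the ideal-mixing expectation maps
  to 0 and a pure like-neighborhood to 1, clamped to [0, 1].
* **Condensed fraction**: proteins in endcap-association clusters of at
  least `min_size` molecules (default 10), where two proteins associate if
  any of their E beads are within **0.6 d0**.  The association distance
  deliberately sits well inside the soft-repulsion core: attractive
  endcap pairs (ε_EE ≈ 0.7 ⇒ a_EE = 8) overlap to r ≈ 0.3–0.5, while
  neutral endcaps crowded at liquid density remain near r ≈ 0.8–1.0.  At
  the interaction range (1.0 d0) the contact graph percolates even for a
  fully dispersed phase at the concentrations simulated here, reading
  ~0.2–0.7 "condensed" where the true value is 0; a cutoff sweep
  (0.5–1.0) shows a plateau over 0.5–0.7 with complete separation
  (0.0 vs ≈ 0.9), and 0.6 is the mid-plateau choice.
* **Adsorbed fraction**: proteins with ≥ 1 E bead within 1.0 d0 of any
  lipid head bead.
* **Circularity**: λ_min/λ_max of the 2D gyration tensor of the largest
  domain's centroids (periodic-aware via circular means); 1 is circular,
  0 collinear.  The eigenvalue ratio equals the squared axis ratio, so a
  2:1 elliptical domain scores 0.25.
* **Protrusion** (informational): 90th-percentile endcap height above the
  upper headgroup plane; distinguishes thin wetting layers from droplets.
* **Membrane gate**: intact iff < 1% of solvent beads lie within 1.5 d0
  of the tail-bead midplane (re-estimated each call) and both leaflets'
  heads remain on their initial sides on average.

**Classifier.**  Membrane axis: DOMAIN when the largest-domain fraction ≥
θ_dom; protein axis: CONDENSED when condensed fraction ≥ θ_cond, else
WETTING when adsorbed fraction ≥ θ_ads, else DISPERSED.  All thresholds
default to 0.5 and are configuration.  The quadrants map to
MIXED_DISPERSED, MIXED_DROPLET, WETTING_DOMAIN and
ADSORBED_DROPLET_DOMAIN; a missing axis (no membrane / no proteins) yields
a PARTIAL_* sentinel.  Exact quadrant boundaries in (ε_EE, ε_EM) are not
asserted anywhere — only the corner behaviors.

## The scaled-down study

The full-size systems (40×40×48 box, ~230,000 beads, 3·10⁶ steps) are far
beyond a desk run, so the `study` module fixes a scaled-down analogue
whose composition preserves the study ratios: an 8×8×14 box, 96 lipids
(80 major / 16 minor — minority fraction 16/96 = 0.1667, all upper
leaflet), 16 B6 proteins (bulk concentration comparable to the larger
systems), 30,000 steps of which the final 20% are averaged for the
equilibrium metrics, and `min_size` = 6 (proportionate to 10 of ~400
proteins at full size).  Corner labels are decided by majority over three
seeds.  The toggling protocol runs 40,000 steps with the
endcap–minority-headgroup attraction switched to ε_EM = 0.8 at 0.2 T_max
and back to 0 at 0.85 T_max; only orderings are asserted (adsorption rises
after switch-on, falls after switch-off, and recovery is faster than the
initial wetting), never absolute times.

What the scaled-down runs do **not** show: quantitative domain line
tensions, the patchy-domain crossover for long backbones (B16), finite
-size-free droplet/dilute-phase coexistence densities, or hydrodynamic
time scales of the full systems.  They do show that the force field,
thermostat and classifier reproduce the four corner morphologies and the
reversibility ordering.

## Known limitations

* No barostat: the box is fixed, so membrane tension is set implicitly by
  the builder's area per lipid (~1.33 d0²).
* The wetting/droplet distinction rests on the 0.6 d0 association
  distance; systems with much weaker self-attraction (ε_EE ≲ 0.3) would
  sit between the calibrated regimes.
* The cell-graph backend emulates the message protocol sequentially; it
  makes no claims about relaxed, truly event-driven message ordering
  beyond distributional equivalence.
* φ0 ≠ 0 bending uses a sin φ-regularized gradient and is untested against
  the φ0 = 0 fast path beyond finite differences, as no molecule here
  uses it.
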