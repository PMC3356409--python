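# Methods

## The model

`iefsim` simulates messenger-protein transport between the cell membrane
(CM) and the nuclear membrane (NM) as an n-body problem with three force
contributions per particle and time step:

1. **Brownian motion.** A Wiener-process walk realised as fixed-length
   steps: each step displaces the particle by ℓ = √(6 D Δt) in a direction
   drawn uniformly on the unit sphere. The diffusion coefficient comes
   from Einstein–Stokes, D = k_B T / (6π η r), with r the Stokes radius.
   At the step scale used, the fixed-length walk reproduces the
   √(6 D t) RMS displacement law exactly (verified by the test suite for
   unconfined walkers, and the confined-walker RMS plateaus below the
   cell radius).
2. **Coulomb interactions.** The charged nuclear membrane is collapsed,
   via Gauss's law, to a point charge Q_N at the cell centre. Forces
   follow Coulomb's law screened by the relative permittivity ε_r = 80:
   F = k q₁ q₂ / (ε_r r²). Every particle interacts with the nucleus and
   with every other free particle (full O(n²) summation; no tree or mesh
   approximation at the n ≤ 2000 scales this package targets). Pair
   separations are clamped from below at the sum of the two Stokes radii
   to avoid the contact singularity.
3. **Stokes drag with a terminal-velocity cap.** Velocities are updated
   by Newton's second law, v ← v + (F/m) Δt, then capped in magnitude at
   the terminal velocity v_t = |F| / b, b = 6π η r, the speed at which
   drag balances the Coulomb force. Because (F/m) Δt exceeds v_t by
   roughly ten orders of magnitude for protein-scale masses, the cap is
   always active for charged particles and the dynamics are effectively
   overdamped. An explicit `overdamped` mode (v = F/b) is provided and
   gives statistically indistinguishable arrival times; this equivalence
   is tested. A particle under zero force has v_t = 0 and stops rather
   than coasting.

Per step and per free particle, in order: charge resampling at the local
pH, force summation, velocity update with cap, drift displacement,
Brownian displacement, boundary handling. Drift and diffusion are applied
as separate sequential displacements so the pure-diffusion statistics can
be validated independently of the field.

## Geometry and boundaries

The cell is a spherical shell: nucleus radius 3 µm, cell radius 5 µm
(shortest CM→NM transit 2 µm). A cubic variant (10 µm side, centred on
the same nucleus) supports face-patch release experiments. The CM
reflects specularly: the segment beyond the wall is mirrored about the
tangent plane at the contact point, preserving path length. The NM
absorbs: a particle whose step crosses the nuclear sphere is pinned at
the crossing point and its arrival time and location recorded.

Whether the NM absorbs is scenario policy. The pulse and diffusion
control experiments use `absorb_all` (every arrival is pinned and
tallied). The MAPK scenarios use `absorb_phosphorylated`: only
phosphorylated particles pin at the NM, and they are released again when
their phosphatase timer strips the phosphates. A permanently absorbing
NM cannot produce steady-state distributions in which free MEK/ERK hover
as mobile particles near the NM and RAF cycles back to the CM, so the
policy is the only reading consistent with both the pulse experiments
and the steady-state distributions; `reflect_all` is also available.

Because step lengths (~10–30 nm) are four to five orders of magnitude
smaller than the shell, boundary tests use the step endpoints; the
probability that a chord dips through a boundary while both endpoints
remain on one side is negligible at this scale (depth ≲ 10⁻⁵ nm).

## Charge speciation

A particle's net charge is resampled every time step from two
independent contributions:

* **IEP term.** The probability of carrying the non-neutral charge state
  is a linear ramp in |IEP − pH| with slope 1/2 per pH unit, clipped to
  [0, 1]: protonated (+1 e) below the IEP, deprotonated (−1 e) above it,
  always neutral exactly at the IEP. The ramp is calibrated to the
  anchor that a protein of IEP 6.7 at pH 6.5 has a 10% chance of
  protonating. A Henderson–Hasselbalch sigmoid cannot reproduce that
  anchor (it gives ~61% for a single site at 0.2 pH units below the
  pK), so the ramp is the speciation model.
* **Phosphate term.** Each phosphate independently carries −1 e or −2 e
  with probability ½ each (expected −1.5 e per phosphate).

Charges are independent across steps (no persistence). Scaffold
complexes take the arithmetic mean of the member IEPs — a KSR1(9.1) +
MEK(6.1) complex has an effective IEP of 7.6, above the entire cytosolic
pH range, which is what moves bound MEK/ERK peripherally — and pool the
phosphates of all members. A literal sum of IEPs is not a pH and was
rejected; the mean reproduces the intended behaviour.

## pH field

Radial profiles: `uniform`; `linear_radial` from pH 7.2 at the NM to
7.4 at the CM (the default for the MAPK scenarios, matching measured
cytosolic gradients); and `double_acidic`, piecewise-linear with both
membrane-adjacent layers acidic (7.2) and a 7.4 maximum at
mid-cytoplasm, for experiments that need acidity at both walls.

## Reference parameter set

The paper-facing dynamical outcomes (pulse transit ~0.01 s mean,
all < 0.05 s; diffusion-only majority-not-arrived at 10 s; RAF return
< 1 s) pin down one consistent parameter set, used as the package
default:

| parameter | value | note |
|---|---|---|
| Δt | 10⁻⁴ s | integration step |
| η | 0.3 Pa·s | effective crowded-cytoplasm viscosity |
| T | 310 K | body temperature |
| Stokes radius | 5 nm | ~50 kDa globular protein |
| mass | 8.3 × 10⁻²³ kg | ~50 kDa |
| b | 2.827 × 10⁻⁸ kg/s | 6π η r |
| D | 1.514 × 10⁻¹³ m²/s | k_B T / b |
| ε_r | 80 | cytosol ≈ water |
| Q_N | 2.513 × 10⁻¹² C | see below |

Q_N is calibrated so that a −2 e particle at r = 4 µm has a terminal
velocity of 200 µm/s. This single calibration simultaneously yields a
drift-only CM→NM transit of ≈ 0.0102 s (closed form
t = (r₀³ − r₁³)/(3A), A = k Q_N |q| e / (ε_r b), the analytic oracle for
the simulated pulse), a diffusion-only mean first passage of ≈ 19 s over
the same shell (so most uncharged particles have not arrived after
10 s), and a +1 e outward return of ≈ 0.02 s.

## MAPK reaction layer

* Ligand binding is a CM cap (default half-angle 15°); RAF within the
  contact radius of the patch gains 2 phosphates (net charge ≈ −2 e at
  cytosolic pH) while the ligand window is open — 30 s in transient
  mode, indefinitely in steady mode.
* Contact transfer: pRAF + MEK → pMEK and pMEK + ERK → pERK fire
  deterministically when a pair is within the 0.1 µm reaction radius.
  pRAF acts catalytically (one pRAF can phosphorylate many MEK — the
  amplification step); targets gain one phosphate per event. No kinetic
  rates are modelled: with ~10–20 nm steps, on-first-approach firing
  approximates diffusion-limited contact.
* Phosphatases are deterministic per-particle 30-s timers, not
  stochastic rates; on expiry all phosphates are removed, the particle's
  charge reverts to IEP-only, and a particle pinned at the NM is
  released (closing the RAF shuttle cycle).
* KSR1 scaffolds bind free MEK and ERK on contact (first-come slot
  occupancy), move as one unit with the mean IEP and pooled phosphates,
  host the cascade, release newly formed pERK, and can be blocked by
  pERK rebinding at a separate site (which shields the scaffold's MEK
  from further pRAF). Scaffolds start pre-loaded with one MEK each:
  MEK is predominantly scaffold-bound in vivo, and in the simulation the
  field segregates free MEK (to the NM) from KSR1 (to the CM) within
  ~50 ms, so on-contact binding alone could never establish the bound
  population.
* Default copy numbers for the steady scenarios are RAF 100, MEK 500,
  ERK 500, KSR1 200 per cell — RAF sparse relative to MEK/ERK, sized for
  full O(n²) force summation at desk scale. The bundled tests and the
  acceptance script run reduced populations (RAF 20, MEK 25, ERK 25,
  KSR1 12) and a reaction-check stride of 5 steps; the medians that the
  ordering checks compare are separated by ~2 µm, far beyond the
  sampling noise of these counts.

## Numerical choices

* Single seeded NumPy generator per run; (config, seed) determines every
  output statistic byte-for-byte (tested).
* Velocity-cap tolerance 10⁻¹² m/s; boundary tolerance 10⁻⁹ µm.
* Absorbed (pinned) particles leave the force sum; they neither exert
  nor feel Coulomb forces. This avoids an artificial charge crust on the
  NM blocking later arrivals. Pinned phospho-particles still participate
  in contact reactions.
* Scaffold-bound members are slaved to the scaffold position and carry
  zero individual charge; the scaffold carries the pooled charge.
* Dedicated vectorised kernels serve the million-step diffusion-only
  experiments (first-passage sampling, free/confined RMS walkers); they
  share the step rule with the main engine but use a radial fold at the
  reflecting wall, which agrees with specular reflection to first order
  at these step lengths.
* The long-horizon confined-RMS check uses Δt = 10⁻³ s; the plateau
  level (R√(3/5) for a uniformly filled sphere) is step-size
  independent.

## What the scenarios emulate — and what they do not

The generator's scenarios reproduce the study conditions: 100-particle
pulses released on a CM cap, diffusion-only controls on identical
release geometry, a 30-s transient ligand window, and continuous-EGF
steady states with and without KSR1. They do not model organelle
obstacles or mitochondrial field perturbations, nuclear-pore
translocation of pERK (arrivals stop at the NM), RAS/GTP exchange
kinetics, receptor internalisation, isoform diversity, hydrodynamic
interactions, or electro-osmotic counter-flows. Passing tests therefore
show that the electrostatic/speciation transport mechanism produces the
reported transit times and spatial orderings under these idealised
conditions — not that real cytoplasm is this simple.

## Known limitations

* The speciation ramp is calibrated to a single printed anchor; its
  shape away from that anchor is a modelling choice.
* Reaction firing is deterministic on contact; true bimolecular kinetics
  would introduce sub-contact-scale rejection probabilities.
* The terminal-velocity cap makes inertia irrelevant; the `mass`
  parameter only matters in the (never-reached) uncapped branch.
* First-passage times from the fixed-step walk carry an O(step length)
  discretisation bias at the absorbing boundary, ~0.5% of the mean here.
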