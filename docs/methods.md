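# Methods

This note records the models and conventions implemented in `ejecta`, the
choices made where the underlying analysis protocol leaves room, and what the
synthetic-data tests do and do not establish.

## Units and data model

Everything internal is nm / ps / amu / eV (1 amu·nm²/ps² = 0.0103642688 eV).
Readers convert on ingestion via a declared `UnitMap` (e.g. Å→nm, fs→ps).
There is no periodic-boundary handling: the simulated sample is a free
hemisphere in vacuum, so all distances are Euclidean. Atomic masses are IUPAC
conventional values to three decimals, stored in a JSON data file so tests are
bit-stable; they give C₁₂H₂₂O₁₁ = 342.297 amu, matching the printed reference
mass 342.3 at one decimal.

Trajectories are LAMMPS-dump-like text (`ITEM:` headers, per-frame column
order taken from the `ATOMS` header, velocities mandatory because the sputter
criterion needs them). Bond tables come either as per-atom neighbor lists
with bond orders (ReaxFF-style) or a simplified `i j bo` dialect. Bond tables
may be saved less often than frames; frames are paired with the
nearest-in-time table and gaps beyond one frame interval are logged.

## Molecule identification and tracking

Molecules are connected components of the bond graph with bond order strictly
above a threshold (default 0.3, exposed because the cut is deliberately low to
tolerate bond stretching). Species are classified per frame by formula only:
exact match to the solvent template → water, to the sample template → intact
trehalose, anything else → fragment. A trehalose transiently missing a
hydrogen is therefore a fragment for that frame; identity tracking bridges
such frames.

Cross-frame identity is not defined by the source protocol, so the package
uses a majority rule: a molecule inherits a stable id when it shares more
than half of the atoms of both itself and its predecessor; anything else gets
a fresh id and a split/merge event is logged. An even split deliberately
creates two new ids.

## Clusters and the sputter census

Contact is strict: minimum inter-atomic distance < 0.3 nm; a pair at exactly
0.3 nm is not in contact. The implementation uses a k-d tree over atoms but is
required (and tested) to equal the all-pairs computation exactly. Cluster ids
are deterministic (smallest member molecule id) so outputs are reproducible.

The ejection criterion has no stated height origin; the surface reference z₀
defaults to the maximum sample-atom z in the initial frame (conservative for a
hemisphere; a top-decile mean is available). A cluster is sputtered when its
COM is ≥ 15 nm above z₀ **and** its COM vz > 0, evaluated at the end of the
impact phase (default 75 ps).

Category allocation: fragment mass always pools into `fragments` and the
residual intact composition is re-categorized (mixed clusters are not covered
by the published taxonomy; this keeps the partition exhaustive). Pure-water
clusters are tallied separately and excluded from the five categories and the
total. Solvated-category mass includes the adjoining waters by default; a
switch moves water mass to the water tally instead, since the yield units do
not state the convention. Yield spread over impacts uses the population
standard deviation (ddof = 0) so a single impact is well-defined.

## Complex lifetimes

A complex trace is created for every sputtered cluster holding exactly one
intact trehalose and ≥ 1 water at its ejection frame (the first frame the
cluster satisfies the sputter criterion — the 320 ps stability clock starts
there, one of several defensible origins; it is exposed via the trace's
ejection time). A water is "in contact" when it belongs to the trehalose's
contact cluster, so chained contact through another water counts — for these
small complexes the cluster and the contact shell coincide.

Stability is the strictest reading: continuous contact with at least one
water from ejection until the first water-free frame (an `allow_gap_frames`
option implements the net-presence alternative). The exclusion filter removes
complexes stable < 320 ps or holding > 1 water at the last frame; a complex
that sheds *all* waters after 320 ps is **included** (only ">1 water at the
end" excludes) and flagged `bare_at_end`. Contact durations are sums over
sampled frames with no sub-frame interpolation, so every recovered time is
exact up to the frame cadence.

## Signal comparison

Simulated complex counts and the experimental intensity series live on the
kinetic-energy-per-molecule axis E_total/n with E_total = 20 keV. Both are
scaled to their maxima and joined on n (not on energy, avoiding float
equality). The deviation threshold (default 0.2 after normalization) that
flags a divergence region is this package's invention; the source analysis
quantifies similarity only verbally. Experimental values are user-supplied
CSV — none are hard-coded, because they exist only as a published figure.

## Electron Monte Carlo

Transport is the standard competing-process scheme: free path ~
Exp(1/Σλ⁻¹(E)), process ∝ its inverse MFP, linear interpolation on the energy
grid (zero below the grid, clamped above). Elastic scattering redirects
(isotropic or none); excitation subtracts a fixed loss; ionization subtracts
the threshold plus a sampled secondary energy and spawns a cascaded secondary
(isotropic). A sampled process the electron cannot pay for (possible in the
interpolation ramp just above threshold) is a null collision, which keeps the
energy ledger exact: E₀ always equals ionization + excitation deposits plus
all terminal kinetic energies, to 1e-9 eV, asserted in tests.

Electrons terminate by leaving the sphere (escape) or dropping below the
11 eV solvation threshold inside. Net cluster charge = ionizations −
electrons solvated inside (the primary may solvate); campaigns keep events
with net charge +1, the charge state of a SIMS projectile. Hydronium count ≡
ionization count and hydronium positions ≡ ionization positions, justified by
the femtosecond H₂O⁺ + H₂O → H₃O⁺ + OH reaction and frozen proton diffusion
in cryogenic ice. The primary enters at the top surface moving −z, laterally
uniform over the projected disk ("axis" and "hemisphere" entry rules are
alternatives).

The physics content is entirely table-driven. Two fixtures ship:

* **Analytic toys** (`make_toy_cross_sections`): constant ionization rate,
  zero-energy secondaries, no deflection — along a chord of length d the
  ionization count is a Poisson(d/λ) censored at the energy cap, the module's
  main oracle (total-variation < 0.01 at 10⁵ events).
* **A synthetic liquid-water stand-in** (`make_synthetic_water_table`),
  clearly labelled as such: literature-magnitude cross sections (number
  density 33.4 nm⁻³; ionization ≈ 1.6×10⁻¹⁶ cm² near 100 eV above a 13 eV
  effective threshold; 8 eV mean excitation loss; momentum-transfer-scale
  elastic treated isotropically; uniform secondary-energy sharing). It lets
  the nanodosimetry campaign run without external data, and it reproduces the
  qualitative picture — ionization concentrated in a near-surface layer,
  multiplicity growing with sphere diameter.

**Known limitation.** The stand-in does not reproduce the reported ≈30%
probability of ≥ 2 hydroniums in a 7 nm sphere: isotropic elastic scattering
confines electrons far more than the strongly forward-peaked real
differential cross sections, so more of the 100 eV is deposited and the
measured multiplicity is ≈0.65. Matching the published number requires the
real track-structure tables (e.g. exported from Geant4-DNA) supplied by the
user as CSV; the corresponding acceptance test asserts the published band
against the stand-in and fails by design rather than being skipped. The
stand-in was fixed from literature magnitudes before any campaign was run and
was not adjusted afterwards.

## Synthetic scenes

Scene kinematics are scripted, not simulated — the package tests the census,
not the physics. The stated world keeps the documented setup where one
exists: 60 nm hemisphere diameter, 45° incidence in the xz plane, 20 keV
total projectile energy (realized exactly in the t = 0 velocities), 75 ps
impact and 900 ps extended phases, 0.3 bond-order and 0.3 nm contact cutoffs,
15 nm sputter height. Where no value is stated the generator chooses once:
frame cadence 15 ps (toy scale; the real save cadence is unpublished),
projectile size ~32 waters, ≤ ~100 frames and ≤ 5000 atoms so full scenes
analyze in under a second.

The trehalose template is a fixed 45-atom C₁₂H₂₂O₁₁ arrangement on a 0.15 nm
grid (internal geometry only matters through its spatial extent) whose bond
chain splits at one designated bond into the two ring-scission half-sugars
C₆H₁₁O₅ + C₆H₁₁O₆. Adjoining waters sit 0.25 nm above the molecule (in
contact), detached waters jump to > 0.5 nm; ejections cross the 15 nm height
exactly mid-way between two frames and detachments happen mid-interval, so
every planted time is recovered exactly at the cadence with no boundary
ambiguity. Events occupy separate lanes and eject vertically, so ejecta never
interact across events; any two molecules closer than 0.1 nm abort
generation. Seeds jitter placements only — planted truths are seed-invariant
and byte-identical files come from identical specs.

What a green synthetic test establishes: the census, lifetime and mapping
machinery is exact on inputs whose truth is known. What it does not
establish: anything about real bond-order noise, recrossing contacts,
thermal motion, or the actual MD yields — those require the original
simulations, which are out of desk-scale reach.
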