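# Methods

## Model overview

`emtcpm` couples two well-established formalisms.  At the cell scale, a 3D
cellular Potts (Glazier–Graner–Hogeweg) model represents each cell as the
set of lattice sites sharing an integer index; the pattern evolves by
Metropolis-accepted pixel-copy attempts against an effective energy with
adhesion, volume-constraint, surface-constraint and chemotaxis terms.  At
the subcellular scale, every cell owns an instance of a four-species
E-cadherin/β-catenin/proteasome network.  The two scales are coupled in both
directions once per Monte Carlo step (MCS): the lattice supplies each cell's
contact fraction to its network as a translocation forcing, and each
network's free β-catenin decides, via a threshold, whether the cell is in
the adhesive epithelial state or the detached mesenchymal state.

### Potts dynamics

A target site and a random neighbour (within the 4th-neighbour shell, 32
offsets in 3D) are drawn; the source index overwrites the target with
probability 1 if the energy change ΔH ≤ 0 and exp(−ΔH/T) otherwise.  Draws
where both sites carry the same index, or where the source falls outside the
(non-periodic) lattice, are no-ops.  One MCS is `nx·ny·nz` attempts.  The
boundary-energy sum runs over the same neighbour shell as copy attempts;
the surface measure s(σ) is always the first-neighbour boundary-link count,
one consistent geometric measure used both for the surface constraint and as
the denominator of the contact fraction.  The medium is index 0 with its own
type row in the contact table and is exempt from shape constraints.  Cells
may fragment (no connectivity constraint is imposed); a diagnostic
`count_fragments` is provided.

Chemoattractant fields are static analytic functions (linear or radial);
there is no reaction–diffusion solver because the experiments only need
fixed gradients.  The chemotaxis term exists only as a per-copy energy
change ΔE = −(μ_src − μ_tgt)(c(target) − c(source)); positive μ biases a
cell up the gradient, which the drift test verifies behaviourally.  By
default only detached (HighBetaCat) cells respond to the gradient.

### Intracellular network

Dimensionless species per cell (concentrations scaled to total E-cadherin):
free cytoplasmic E-cadherin E, free β-catenin B, membrane complex C,
β-catenin–proteasome complex Q; free proteasome is implied as P₀−Q.

    dE/dt = −k₁ φ E B + (J⁻ + d_eff) C
    dB/dt =  α − k₁ φ E B + (J⁻ + d_eff) C − κ B (P₀−Q) + k₋ Q
    dC/dt =  k₁ φ E B − (J⁻ + d_eff) C
    dQ/dt =  κ B (P₀−Q) − (k₋ + ν) Q

with φ = [attached]·J⁺ and d_eff = d while attached, d·boost while detached.
The forcing pair is the half-rectified rate of contact-area change,
J⁺ = p₊·max(ġ,0), J⁻ = p₋·max(−ġ,0), sampled once per MCS after the sweep
(ġ is a backward difference of the contact fraction over one MCS, with one
MCS equal to dt = 0.03 dimensionless time).  Both adhesion branches live in
a single right-hand side and are selected by zeroing parameters, not by
swapping model files, so a branch switch never re-creates the integrator.

Two design points deserve emphasis:

* **Formation is gated, release is not.**  Complex formation (k₁ φ E B)
  requires the attached state — membrane bond assembly needs cell–cell
  contact.  The contact-loss release term J⁻·C, however, acts in *both*
  branches: bonds broken by a shrinking contact dump their cadherin and
  β-catenin back into the cytoplasm whether or not the cell has crossed the
  EMT threshold.  This is the mechanism by which one cell's detachment
  raises free β-catenin in its still-attached neighbours and lets
  detachment propagate as a wave; gating release on the detached state
  would leave below-threshold cells blind to the loss of their neighbours.
* **Conservation structure.**  E + C (total cadherin) and Q + (P₀−Q)
  (total proteasome) are exactly conserved; β-catenin is produced at α and
  degraded only through the proteasome complex at ν.  The conserved
  combinations are derived symbolically (sympy) from the implemented
  right-hand side and re-checked numerically in the tests, so any future
  edit to the kinetics that breaks the moiety structure fails loudly.

Integration uses an adaptive Cash–Karp embedded Runge–Kutta 4(5) vectorised
across all cell instances (rtol 1e-8, atol 1e-10), validated against tight-
tolerance `scipy.integrate.solve_ivp` solves.  Concentrations are clipped at
zero after a step (stochastic contact signals can push explicit steps
marginally negative); clip events are counted in the run manifest.

### EMT/MET switching and schedule

Free β-catenin is checked for every cell each MCS after integration.
Strictly above the threshold while attached: the cell's type becomes
HighBetaCat (weakly adhesive contact-energy row), the formation gate closes
and the dissociation boost opens.  Strictly below while detached: the
reverse (MET).  Comparisons are strict so a cell exactly at threshold keeps
its mode (avoids chatter).  Network integration and threshold checks are
suspended before `integration_start_mcs` (default 20) because the initial
gap-closing transient produces contact-area changes that do not reflect any
biology.  EMT is induced by lowering κ (the β-catenin–proteasome binding
rate) for every cell at `trigger_mcs` (default 70 in the layer scenario).

### Growth, mitosis, removal

During growth phases each attached cell's targets are incremented per MCS at
constant fractional rates of its *current* volume and surface
(Vt += r_v·v, St += r_s·s; defaults 0.02 and 0.0133, i.e. surface grows at
two-thirds of the volume rate to keep shapes feasible).  A cell divides when
its volume exceeds `division_multiple` (default 2) times its volume at
creation: its pixels are split by a uniformly random plane through the
centroid (bounded re-draws if a side is empty), both halves receive half the
pre-division targets, and the child gets a deep copy of the parent's network
state.  The population cap bounds the total number of cells ever created, so
growth and division stop permanently once it is reached and the cumulative
removed-cell count can never exceed it.  The invasion assay deletes any cell
whose centroid travels beyond a set distance from the initial layer plane
(layer scenario) or the lattice centre (spheroid); removed pixels revert to
medium and the cell's network is disposed.

## Parameters

Dimensionless kinetic defaults (all overridable per scenario):

| symbol | package name | default | role |
|---|---|---|---|
| k₁ | `binding_ecad_bcat` | 20 | complex formation rate |
| κ | `binding_bcat_proteasome` | 5 → 1 (trigger) | proteasome binding; the EMT trigger lowers it |
| k₋ | `dissoc_bcat_proteasome` | 0.1 | proteasome complex dissociation |
| ν | `degradation_nu` | 0.4 | β-catenin degradation in the proteasome; the invasiveness dial |
| α | `production_alpha` | 0.1 | β-catenin production |
| d | `dissoc_complex_d` | 0.2 | basal complex dissociation |
| boost | `detach_dissoc_boost` | 10 | dissociation acceleration on detachment |
| β_thr | `threshold_beta` | 0.18 (0.4 spheroid) | EMT/MET threshold on free β-catenin |
| p₊, p₋ | `p_plus`, `p_minus` | 1, 2 | translocation responsiveness to contact change |
| P₀, E₀ | totals | 1, 1 | conserved proteasome and cadherin totals |

These values were chosen as a self-consistent set around the closed-form
contact-free steady state  B* = (k₋+ν)(α/ν) / (κ(P₀ − α/ν)):

* pre-trigger (κ = 5): B* ≈ 0.033, far below every threshold — an
  untriggered run can never produce EMT;
* post-trigger (κ = 1, layer): B* ≈ 0.167, just below β_thr = 0.18 — cells
  sit close under the threshold and stochastic contact fluctuations push
  individual cells over, from which detachment propagates as a wave
  (initiation is random by construction, matching the stochastic character
  of the lattice model);
* detached cells relax back to B* < β_thr, giving MET and sustained
  detach–reattach cycling in the layer;
* the spheroid scenario triggers deeper (κ → 0.25) with a higher threshold
  (0.4 during growth, so divisions never cause spurious EMT), putting the
  post-trigger steady state *above* threshold: every surface cell crosses
  deterministically and detached cells do not re-attach, which is the
  regime the invasion assay measures.

ν = 0.25 / 0.4 / 0.8 are used as the slow/medium/fast degradation levels:
slower degradation keeps free β-catenin higher for longer, cells detach
earlier and farther, and the removed-cell count is larger.  The assay is
deliberately sensitive to small ν changes (the steady state has a pole at
ν = α/P₀).

Potts defaults: T = 8, λ_v = 2, λ_s = 0.5, 4th-neighbour shell.  Contact
energies: J(Low,Low) = 3, J(Low,Medium) = 8 (epithelial cells strongly
prefer each other), J(High,·cell) = 14, J(High,Medium) = 4 (detached cells
prefer medium and actively separate).  Cells start as 5³ cubes with a
1-pixel gap; the initial target volume is 1.728× the cube (216 = the
confluent 6³ pitch volume, so the sheet closes its gaps and becomes
confluent during equilibration) and the target surface is the matching 216.

## Scenarios and scales

The three drivers use desk-scale geometries chosen so a full experiment runs
in seconds on one CPU; larger lattices are plain config values.

* `layer_waves`: 10×10×1-cell sheet on a 64×64×10 lattice, 600–1500 MCS,
  no growth, no chemotaxis.  Shows trigger-induced detachment waves (peak
  detached fraction 1.0 around MCS 550–600) and MET cycling on longer runs.
* `tumour_layer`: 4×4×1 seed layer on 40×40×36, growth to a 40-cell cap,
  linear gradient along z, removal at 12 pixels from the layer plane,
  1200 MCS.
* `mts`: one central cell on 40³, growth to 40 cells (spheroid radius ≈ 10
  px), radial gradient, removal at 14 px, 900 MCS (1200 for the
  cell-position trace study, whose tracked cell is the first cell removed
  in the fastest-invading run — an id that exists in every run because
  pre-trigger dynamics are identical across ν at fixed seed).

The radius analysis reads the spheroid radius as the mean over the last
low-variance window of a tracked cell's distance-to-centre trace (rolling
window, lowest-30%-variance criterion) and the departure onset as the first
sustained exceedance of that plateau by 1.5 px.

## What the generator does and does not emulate

Synthetic initial conditions are deterministic cube packings; all
variability comes from the seeded Metropolis dynamics.  The model does not
represent extracellular matrix, haptotaxis, secreted/diffusing fields,
apoptosis, nuclear/cytoplasmic β-catenin compartments, or physical-time
calibration (MCS and the dimensionless network time are related only through
dt = 0.03 per MCS).  Passing tests therefore demonstrate the internal
consistency of the coupled mechanism — threshold-switched adhesion driven by
contact-dependent kinetics — under idealised conditions, not quantitative
agreement with any particular cell line.

## Numerical and engineering choices

* All stochastic choices (site/neighbour draws, Metropolis decisions,
  division-plane orientations) consume one explicitly seeded xorshift64*
  stream, so runs are bit-identical for a given (config, seed); the seed is
  recorded in the run manifest.
* The sweep kernel maintains volumes, surfaces, centroid sums and the total
  energy incrementally; agreement with from-scratch recomputation (1e-6
  relative) is a continuously tested invariant, and divisions/removals
  trigger an exact energy re-evaluation.
* The Metropolis engine and contact counting are numba kernels (~10⁷ copy
  attempts/s on one core); kinetics are vectorised numpy across all cells.
* Per-cell network instances live in per-model arrays inside the registry;
  an instance is a row, so mitosis copy is a row copy and the κ trigger is
  a column assignment that reaches every instance before its next step.
* Models can also be loaded from a small SBML subset (species, parameters,
  reactions whose kinetic law is a plain product — mass action); a bundled
  file expresses the built-in network in that form with the free proteasome
  explicit, and a test holds the two forms to the same trajectories.
  Unsupported SBML constructs raise a named error.

## Known limitations

* EMT initiation in the layer regime is fluctuation-driven by design; the
  time of the first crossing varies by a few hundred MCS across seeds.
* The invasion assay saturates at the population cap on long horizons — the
  ν-ordering is sharpest at the default assay lengths.
* The Potts temperature, contact table and λ values are a coherent regime,
  not a fit to data; changing one of them (e.g. stiffening λ_s) rescales the
  contact-fluctuation amplitude that drives threshold crossings and may
  require re-balancing β_thr or κ_after.
* Lattice boundaries are closed; scenarios keep cells away from the edges,
  and a cell reaching the boundary would see its neighbourhood truncated.
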