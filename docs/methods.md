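# Methods

## Scope and model family

`supramol` studies the *dynamic equilibrium* of one-dimensional
supramolecular polymers: fibres whose monomers are held by reversible,
non-covalent interactions and which, once the average structure has
equilibrated, keep exchanging monomers and fragments with each other and
with the free pool.  Three coarse-grained monomer species are implemented.

**M** — a minimalistic directional monomer: seven beads, six shielding
beads at the vertices of a regular hexagon (edge 0.47 nm) around one core
bead.  The flat geometry is imposed by harmonic bonds: nearest-neighbour
ring bonds and core spokes (k = 20,000 kJ mol⁻¹ nm⁻², r₀ = 0.47 nm) and
three opposite-vertex cross-braces (k = 15,000 kJ mol⁻¹ nm⁻², r₀ =
0.94 nm).  Non-bonded interactions are Lennard-Jones with a single bead
diameter σ = 0.47 nm; core–core wells of ε = 40–50 kJ mol⁻¹ (several
k_BT at 300 K) drive face-to-face stacking, while shield beads interact at
only 0.2 kJ mol⁻¹ and screen lateral approach, making the attraction
directional.  The spokes are not strictly necessary for planarity (the
braces handle that) but pin the core at the hexagon centre; they are a
package choice, replaceable by parsing an external ITP.

**BTA** — an 18-bead discotic monomer representative of
benzene-1,3,5-tricarboxamide-like motifs in a good solvent: a central core
bead carrying a rigid dipole of two ±1.4 e charge beads along the stacking
axis, plus three five-bead solvophilic arms.  LJ wells: arm–arm 1, arm–core
0.5, core–core 2.5 kJ mol⁻¹; the charge beads have no LJ interaction and
couple only electrostatically (truncated-shifted Coulomb, relative
dielectric 15), which imparts the head-to-tail directionality of amide
stacks.  Self-assembly strength is controlled through temperature
(300–340 K) rather than ε.

**BTA_w** — structurally identical to BTA but amphiphilic: the six
innermost arm beads (two per arm) form a solvophobic collar whose mutual ε
is raised from 1 to 4 kJ mol⁻¹.  This adds a non-directional attraction
channel, which is what populates the fibre bulk with exchange-active
defects.

Bonded constants not fixed by the model geometry are defaults: arm bonds
k = 1250 kJ mol⁻¹ nm⁻² (r₀ = 0.47 nm), arm angles k = 25 kJ mol⁻¹ rad⁻²
at 180°, inter-arm angles at 120° and dipole–arm angles at 90° (same k),
and a stiff antipodal dipole angle (k = 500).  The extra angle terms exist
so that the reference geometry is a mechanical minimum — every bond and
angle is exactly at rest in the built conformation, so an isolated monomer
has zero bonded energy (asserted to 1e-9 kJ mol⁻¹).  Bead masses are
72 amu (36 amu for charge beads), the standard 4-to-1 CG convention; every
observable analysed here is configurational, so masses only set the time
mapping.

## Dynamics

Implicit solvent enters through Langevin friction and noise only (NVT).
The integrator is the BAOAB splitting with friction γ = 1/τ_t, τ_t =
0.1 ps, and Gaussian noise satisfying fluctuation–dissipation at the
target temperature; time steps are 20 fs (M) and 15 fs (BTA/BTA_w).
Non-bonded potentials (LJ and Coulomb alike) are truncated and shifted to
zero at r_c = 1.1 nm under the minimum-image convention in a cubic
periodic box.  Intra-monomer pairs within two bonds are excluded from
non-bonded interactions (nrexcl = 2; for the M hexagon this excludes all
intra-monomer pairs, since every pair is within two bonds via the core).

Two force paths exist deliberately.  The public `potential_energy` /
`forces` functions are plain vectorised all-pairs NumPy — simple enough to
audit and cheap at analysis scale.  The integrator uses a numba-compiled
kernel with a Verlet pair list (cutoff + 0.3 nm skin, rebuilt when any
bead moves more than half the skin); a test requires its forces to match
the all-pairs path to 1e-10, and forces are verified against central
finite differences of the energy to 1e-4 relative.  In the zero-noise,
zero-friction limit the splitting reduces to velocity Verlet; total energy
drift of a bound dimer is below 0.1% over 10⁵ steps.

The engine is intended for reduced systems (tens of monomers, tens of
ns).  The full-scale reference systems — 500 monomers in a
22.056 nm box (density 0.0466 nm⁻³, ≈77 mM) for tens of microseconds —
are supported through the GROMACS export path: `write_gromacs_inputs`
emits GRO/ITP/TOP/MDP (integrator `sd`, τ_t = 0.1 ps, potential-shifted
cutoffs at 1.1 nm) and trajectories come back in via GRO sequences, XTC
(through MDAnalysis) or the internal HDF5 layout.

## Analysis

**Assemblies.** Two monomers are in contact when their core beads lie
within r_cut = 0.6 nm — a radius enclosing the first peak of the
core–core g(r); 0.7 nm is the robustness value.  Assemblies are connected
components of the contact graph (scipy sparse graph machinery over a
periodic k-d tree); assemblies may wrap the box and are never unwrapped,
which is safe for size and contact statistics.  The coordination number
φ = 2·(edges)/N is 2 for an ideal infinite or ring-closed stack, 2(n−1)/n
for a linear n-mer.  Size histograms use logarithmic classes {1}, {2},
{3–4}, …, {257–512} (linear grouping retained for comparison), reported
both as percentage of monomers (mass-weighted) and of assemblies.

**Traffic and flux.** Binding b(t) and unbinding u(t) events between
consecutive sampled frames give the cumulative per-monomer traffic
T(τ) = Σ(b+u)/N and flux F(τ) = Σ(b−u)/N.  At equilibrium F plateaus
while T keeps growing — the package's operational signature of a dynamic
equilibrium.  The default event definition is contact-edge creation/loss
(symmetric, frame-local, relabelling-independent); an alternative
membership-overlap mode exists for sensitivity analysis.  Events within
one sampling interval that cancel are invisible, so the sampling interval
(Δτ = 300 ps for the reference systems) must stay short relative to the
inter-event time.

**Transition matrices.** Monomer moves between size-i and size-j
assemblies at lag Δτ accumulate in a raw matrix (diagonal = persistence),
symmetric at equilibrium by detailed balance — the implementation asserts
an L1 asymmetry below 0.05 on a stationary kinetic Monte Carlo trajectory
of 200 monomers sampled 5×10⁴ times, where the bound is sampling error,
not physics.  Row normalisation yields the probability matrix (symmetry is
lost by construction).  Dividing above-diagonal entries by the row size
and below-diagonal entries by the column size converts monomer counts to
assembly-level binary events; this assumes each transition involves
exactly two assemblies, which holds when Δτ is short (the KMC oracle
recovers 2× the logged event count within 1% at fine sampling, and
degrades visibly at coarse sampling — quantified in the tests).

**Mechanism classification.** Each binary event has partner fragment
sizes p1 ≤ p2 (for a matrix entry (i, j): the smaller assembly and its
complement |i−j|).  With thresholds A = ⟨size⟩ (time-averaged mean
assembly size, N/⟨number of assemblies⟩, rounded) and E = max(2,
round(A/5)): yellow = small species with a sub-A partner, green = small
species with a large fibre, red = medium–medium coalescence/fragmentation,
blue = large–large.  Yellow+green+red versus blue summarises communication
via small species versus via large-fragment fission/fusion.  Diagonal
entries are excluded; classification always uses exact sizes (grouping is
display-only).  Raising A provably only drains the blue class — a
monotonicity test.

**Tip versus bulk exchange.** Contact degree labels each monomer tip
(degree ≤ 1), ordered bulk (2) or defect (≥ 3, plus degree-1 monomers
dangling from a branch point).  Each unbinding event inherits the leaving
monomer's label in the frame before the event (binding: the arriving
monomer's label after); the leaving/arriving monomer is the endpoint that
ends up in the smaller cluster.  This attributes tip detachments to tips
and mid-fibre extractions to the bulk by construction.

## Synthetic ground truth

The Gillespie KMC generator evolves a set of linear chains: merges join
two chains end-to-end at a constant per-pair rate, fragmentations break a
uniformly chosen internal bond at a per-bond rate (both kernels
pluggable).  The process conserves monomers exactly, satisfies detailed
balance on chain partitions, and relaxes to a nontrivial stationary size
distribution; every event is logged with exact partner sizes.  Because
chains carry an internal bond structure, contact-edge analyses apply
verbatim, and merge/fragment events map one-to-one onto edge
creation/loss.  The shared test fixture uses N = 200, k_merge = 0.02 per
pair, k_frag = 0.05 per bond, 5×10⁴ samples at 0.02 time units (mean
inter-event interval ≈ 0.06, so the binary-event assumption holds), with
the first 100 time units discarded.

What the KMC does *not* emulate: geometry (no positions, so φ, g(r) and
tip localisation are tested on deterministic geometric fixtures instead),
size-dependent diffusion, and correlated multi-event cascades.  Passing
the KMC oracles therefore validates the bookkeeping of the analysis
chain, not the physics of any particular force field.

## Reduced-scale physics checks

Desk-scale runs cannot reach the reference systems' equilibrium (tens of
microseconds).  The ε-trend check therefore uses 20 M monomers at the
reference density (box 7.55 nm), 20 ns at 300 K, started from two
pre-stacked 10-mers — the "S" initial condition — with identical seeds for
both ε values.  From that side of equilibrium the relaxation direction
exposes the equilibrium ordering well before convergence: at ε = 40 the
fibres measurably fragment and re-form (higher traffic slope, smaller
time-averaged mean assembly size over the second half) while at ε = 50
they do not.  These runs take a few minutes; their durations and sizes
are package choices balancing statistical clarity against test runtime.

## Numerical details and limitations

* Contact detection, pair lists and g(r) use `scipy.spatial.cKDTree` with
  periodic boxsize; coordinates are wrapped into [0, L) first.
* Probability-matrix rows with no observations are NaN and excluded from
  reports rather than silently zeroed.
* The angle-force kernel guards sin θ ≥ 1e-8; at exactly θ = θ0 = 180°
  the prefactor vanishes so the guard never biases forces.
* Langevin noise uses numba's global RNG seeded per run; trajectories are
  bit-reproducible for a fixed seed within one platform/build.
* Electrostatics are cutoff-based by design (1.1 nm, ε_r = 15); no Ewald
  summation.  This matches the model contract but means long-range dipole
  correlations are absent.
* The engine has no constraints, pressure coupling or GPU path; it is a
  correctness-first reference implementation, not a GROMACS replacement.
* Mechanism percentages depend on A and E; the defaults follow the
  mass-weighted mean-size convention above, and the thresholds are
  explicit inputs everywhere so alternative conventions can be tested.
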