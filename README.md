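# supramol

Coarse-grained modelling and equilibrium exchange-dynamics analysis for
supramolecular polymers.

Supramolecular fibres — one-dimensional assemblies of monomers held
together by reversible stacking, dipolar or solvophobic interactions — are
not static objects at equilibrium: they continuously exchange monomers and
fragments with each other and with the free pool.  `supramol` is a toolkit
for quantifying that dynamic equilibrium.  It is aimed at molecular
modellers who want to (a) simulate minimalistic self-assembling monomer
models at reduced scale, (b) export full-scale systems to GROMACS, and
(c) analyse either kind of trajectory with a common statistical pipeline.

## What is in the box

* **Models** (`supramol.models`) — three monomer species: the hexagonal
  directional monomer **M** (7 beads; core–core Lennard-Jones well
  ε = 40–50 kJ/mol, σ = 0.47 nm, weakly interacting shielding beads), the
  discotic **BTA** (18 beads; central ±1.4 e dipole, three solvophilic
  arms) and the amphiphilic **BTA_w** (solvophobic inner-arm collar,
  ε = 4 kJ/mol).  Random-gas ("R") and pre-stacked-fibre ("S") initial
  configurations.
* **Engine** (`supramol.engine`) — implicit-solvent Langevin (BAOAB)
  dynamics, friction γ = 1/τ_t with τ_t = 0.1 ps, truncated-shifted
  non-bonded potentials at 1.1 nm, periodic cubic box, numba-accelerated
  Verlet pair list verified against an all-pairs oracle.
* **Analysis** (`supramol.clustering`, `supramol.exchange`,
  `supramol.transitions`) — contact-based assembly detection
  (r_cut = 0.6 nm between cores), size distributions, coordination number
  φ, g(r), cumulative molecular traffic and flux

      T(τ) = Σ_{t≤τ} (b(t)+u(t))/N,    F(τ) = Σ_{t≤τ} (b(t)−u(t))/N,

  monomer/probability/assembly transition matrices at lag Δτ, the
  yellow/green/red/blue mechanism classification with size thresholds
  A = ⟨size⟩ and E = A/5, tip-versus-bulk exchange localisation, and
  size-class interconnection graphs.
* **Synthetic ground truth** (`supramol.synthetic`) — deterministic
  geometric fixtures (ideal/ring/branched fibres, dispersed gases) and an
  exact Gillespie aggregation–fragmentation simulator with a full event
  log, so every analysis operation is testable without MD.
* **I/O + CLI** (`supramol.fileio`, `supramol.cli`) — GROMACS-dialect
  GRO/ITP/TOP/MDP export and parsing, HDF5 trajectories, membership TSV,
  and a `supramol` command with `build`, `simulate`, `export-gromacs`,
  `cluster`, `traffic`, `transitions`, `mechanisms` and `kmc` subcommands.

## Worked example

Generate a stationary aggregation–fragmentation trajectory (200 monomers)
and ask how its assemblies communicate:

```python
from supramol import synthetic, exchange, transitions
from supramol.clustering import MembershipTrajectory

params = synthetic.KMCParams(n_monomers=200, k_merge=0.02, k_frag=0.05,
                             t_end=600.0, sample_dt=0.02, seed=7)
membership, events = synthetic.run_kmc(params)
stationary = MembershipTrajectory(membership.frames[5000:])  # drop burn-in

print("mean assembly size:", round(stationary.mean_assembly_size(), 2))

ev = exchange.detect_events(membership)
tf = exchange.traffic_flux(ev, 200)
print("traffic T(end) = %.2f, flux F(end) = %.3f" % (tf.traffic[-1], tf.flux[-1]))

mats = transitions.compute_transition_matrices(stationary)
rep = transitions.classify_mechanisms(mats.assembly, membership=stationary,
                                      config=transitions.TransitionAnalysisConfig())
print("A =", rep.A, "E =", rep.E)
print({c: round(p, 1) for c, p in rep.percentages.items()})
```

prints

```
mean assembly size: 6.78
traffic T(end) = 51.93, flux F(end) = 0.870
A = 7 E = 2
{'yellow': 16.2, 'green': 11.7, 'red': 58.3, 'blue': 13.9}
```

Read: each monomer took part in ~52 binding/unbinding events while the
net flux stayed below one event per monomer — assemblies of stable
average size (≈7 monomers) in constant exchange, i.e. a dynamic
equilibrium.  Off-diagonal exchange events split into communication via
small/medium species (yellow+green+red ≈ 86%) versus coalescence and
fragmentation of large assemblies (blue ≈ 14%) for these rate constants.

The same pipeline runs on geometric trajectories; for example, the
coordination number of a perfectly stacked ring fibre,

```python
from supramol.clustering import coordination_number
from supramol.synthetic import make_fixture
coordination_number(make_fixture("ring_fibre", 30, 0.5, 22.056))  # -> 2.0
```

is exactly 2, the signature of a defect-free infinite stack.

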