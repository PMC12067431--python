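# Methods

## Model and units

The system is an implicit-solvent bead–spring model of `n_d` cationic
dendrimers, `n_s` anionic surfactant chains and their counterions in a
cubic periodic box. All quantities are reduced with the thermal energy at
room temperature as the energy unit (ε_u = k_B·T_r, T_r = 298 K) and the
Bjerrum length of water as the length unit
(σ_u = λ_B(ε_r, T_r) = e²/(4πϵ₀ε_r k_B T_r) ≈ 6.92 Å at ε_r = 81). Two
consequences anchor the unit system and are recomputed by
`scripts/acceptance.py`: the reduced elementary charge e* = √ε_r = 9
(so that e*² z_i z_j /(ε_r r*) equals the thermal Coulomb energy), and the
LJ time unit t_u = σ_u·√(m_u/ε_u) ≈ 2.41 ps for a bead mass of 30 g/mol.

A dendrimer is grown from a two-monomer core; each core monomer sprouts two
spacers, every interior branch point is trifunctional (one incoming, two
outgoing spacers of `S` bonds each), and the nodes `G` spacers from the
core are the +1e terminals. Terminal and monomer counts are properties of
the constructed tree — N_t = 2^(G+1), N_d = 2 + 2S(2^(G+1) − 2) — not
inputs. Surfactants are 4-bead chains (−1e head, three tails). Counterion
counts (n_d·N_t anions, n_s cations) follow from exact electroneutrality,
which `assemble_system` asserts.

Interactions: truncated-and-shifted LJ 12-6 (tail–tail strength ε*, cutoff
2.5σ; all other pairs ε* = 1 with the WCA cutoff 2^{1/6}σ, i.e. purely
repulsive good-solvent conditions), FENE bonds (k* = 30, R0* = 1.5; bonded
pairs keep their LJ term, the standard bead–spring combination), and
Coulomb λ_B*·z_i z_j/r with λ_B* = 1 by the choice of length unit. The
tail–tail strength ε* ∈ {1.25, 1.5, 1.6} is the hydrophobicity dial and the
only interaction parameter varied.

## Integrator

Underdamped Langevin dynamics are discretized with BAOAB splitting
(half-kick, half-drift, exact Ornstein–Uhlenbeck velocity refresh,
half-drift, half-kick) at Δt* = 0.005 and γ* = 1. With γ* = 0 the scheme
reduces exactly to velocity Verlet, which the NVE energy-drift check
exercises (< 10⁻³ ε_u per bead over 10⁴ steps on a WCA gas). The measured
stationary kinetic temperature of a 50-bead gas over 2×10⁵ steps sits
within 2% of T* = 1. All randomness flows through one numpy Generator
whose bit-generator state is checkpointed, so a restarted run extends the
uninterrupted trajectory bitwise.

Pair forces are evaluated over Verlet lists with a 0.4σ skin, rebuilt when
any bead has moved more than skin/2 since the last build; the evaluation
applies exact cutoffs, so the lists are a pure optimization. The lists are
built by an O(N²) minimum-image pass compiled with numba — at desk scale
(≲ a few thousand beads, Coulomb cutoff 10σ in boxes of L* = 30–70) cell
lists would not pay for themselves. A one-shot zero-skin path
(`compute_forces`) serves as the reference in gradient and list-consistency
tests (central differences agree with analytic forces to 10⁻⁶ relative).

Electrostatics in the desk-scale integrator use the plain truncated
Coulomb potential at the real-space cutoff 10σ. The mesh solver named by
the original protocol is treated as a tolerance contract: the package's
Ewald solver reproduces an independent, very conservatively parameterized
Ewald reference to < 10⁻⁴ relative force error on 200 charges, and the
rock-salt Madelung constant to 10⁻⁶. Full Ewald inside the integrator is
supported in principle (the solver returns forces) but is not used in the
desk presets for cost reasons; the desk-scale acceptance check is a
direction-of-effect test and is insensitive to the k-space tail.

## Initial configurations

Dendrimers are placed by self-avoiding breadth-first growth along the bond
tree (bond length 0.97σ, 40 trials per bead with a relaxing overlap
threshold), surfactants as random rigid rods, ions uniformly; a soft-core
push-off then iteratively separates all nonbonded pairs to ≥ 0.9σ while
holding bonds near 0.97σ, raising `PackingError` if it cannot. Equilibrium
statistics are initialization-independent, so the protocol only needs to
produce a valid, reproducible (seeded) starting point.

## Cluster taxonomy

One contact distance r* = 1.5σ governs every criterion, applied strictly
(< r*) to minimum-image distances:

* chains are bound when any tail–tail pair of two distinct chains is
  closer than r*; micelles are connected components of that graph (mass 1 =
  unimer);
* a micelle binds a dendrimer when any member head is closer than r* to
  any terminal; 0/1/≥2 bound dendrimers classify it free/corona/bridge (a
  single chain touching terminals of two dendrimers is a mass-1 bridge);
* mixed clusters are connected components of the bipartite
  micelle–dendrimer graph; unbound dendrimers become (0,1) aggregates and
  free micelles (s,0) aggregates, so aggregates partition all polymer
  beads in every frame;
* a counterion closer than r* to any bead of an aggregate is condensed.
  When several aggregates qualify, the default assigns it exclusively to
  the aggregate owning the nearest bead. This choice (the source protocol
  does not address multiplicity) is what makes the per-frame charge ledger
  exact: Σ over aggregates of ch = d·N_t − s + n_sc − n_dc, plus free-ion
  charges, is identically zero. A `shared` mode that credits every
  qualifying aggregate is available but breaks the ledger by design.

The production path uses periodic KD-trees and sparse connected
components; `dendrisurf.bruteforce` reimplements every stage with full
O(N²) distance matrices and a hand-written BFS, and the two are asserted
equal (together with planted labels) on 100 fuzzed planted frames.

## Aggregate statistics

Aggregates are indexed by n_{s,d} = d·n_s + s for s > 0 and n = 0 for a
free dendrimer; the inverse d = (n−1) div n_s, s = n − d·n_s is verified as
a bijection by exhaustive round trip (n_s = 600, d ≤ 2). Per-frame
histograms (absorbed count, free micelles, free unimers, free dendrimers,
mixed clusters) and observation histograms (free/bridge/corona micelle
masses, the index histogram) use unit integer bins. Index-conditioned
means (bridge/corona number and mass, condensed counts, effective charge)
are reported only for indices observed strictly more than ten times — the
statistical-reliability filter — with occurrence counts always exposed so
users can add their own uncertainty estimates (none are reported upstream).

Favored clusters: within the d-range d·n_s < n ≤ (d+1)·n_s, a bin is a
local maximum if it strictly exceeds its nearest nonzero-count neighbors
(zero-count gaps merged); the highest such maximum defines the favored
index, ties resolving to the lower index with a warning; an optional
window-3 moving average (off by default) can pre-smooth. An empty d-range
(e.g. d = 2 at weak hydrophobicity) is reported as absent rather than an
error.

## Planted configurations

The synthetic generator states an aggregate decomposition (micelle masses,
attachment sets, condensation targets) and realizes it on a coarse block
grid: micelle tails in 1.2σ columns (adjacent columns bound), dendrimer
beads in a 1.0σ lattice, blocks separated by ≥ 2.2σ, binding realized by
teleporting a head and a terminal to a shared porch site 1.2σ apart,
condensed ions placed 0.7σ from an interior anchor bead of their target.
Intended contacts therefore sit at ≤ r* − margin and unintended pairs at
≥ r* + margin (margin 0.2σ by default), making every classification
unambiguous. Planted frames are fixed points of the analysis —
analyze(plant(spec)) equals the planted labels for all fuzzed specs — which
is the package's strongest correctness guarantee for the taxonomy code.
What planted frames deliberately do not emulate: thermodynamic micelle
geometry, realistic densities, or dynamical correlations. A green planted
test therefore validates classification logic and bookkeeping, not the
physics of self-assembly; the latter is exercised by the scaled-down
dynamical scan.

## Desk scale versus full scale

The published protocol (two dendrimers, 600 chains, L* = 70, 10⁶ + 10⁷
steps per state point) is supported as a long-running mode
(`scripts/full_scale.py`, which ends in the identical analysis pipeline and
summarizes f_s, unimer probability, favored clusters, ⟨m_br⟩, ⟨m_fmic⟩ and
effective charges). The test suite instead runs a reduced system — one
G3S4 dendrimer, 60 chains, matching counterions, L* = 30, 2×10⁵ steps per
hydrophobicity — and checks directions of effect: f_s increases
monotonically across ε* ∈ {1.25, 1.5, 1.6} and free micelles are dominated
by unimers at ε* = 1.25 (measured ratio ≈ 0.87). Absolute desk-scale
values are far below full scale (f_s ≈ 0.07 at ε* = 1.6 versus ≈ 0.8 for
G7 at full scale): one small dendrimer offers 16 binding sites against 60
chains and the runs are short; only trends transfer.

## Numerical choices and limitations

* Strict inequalities at r*; planted margins keep tests off the boundary,
  and for thermal configurations the boundary is measure-zero.
* Ewald parameters derive from the requested accuracy (erfc(α·r_c) and the
  k-space Gaussian tail both pushed below it); rc defaults to L/2.
* The assembly push-off targets 0.9σ minimum separation (the contract is
  ≥ 0.8σ) so that the first integration steps see moderate forces.
* Desk Coulomb truncation at 10σ neglects the k-space tail; quantitative
  charge-sensitive observables at full scale should use the Ewald solver.
* No pressure coupling, explicit solvent, charge regulation, density
  profiles or shape descriptors; histogram estimates carry no error bars
  (occurrence counts are exposed instead).
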