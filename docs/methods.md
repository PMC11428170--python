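# Methods

`gdsfold` generates ensembles of protein-folding pathways as sequences of
inter-residue contact maps, back-maps them to coarse-grained bead
structures, refines them into minimum-energy paths, and clusters them by
mechanism.  This note records the models, the tunable parameters and the
numerical choices, and what the synthetic test system does and does not
show.

## The BLN force field

Each residue is one bead classed Hydrophobic (B), Hydrophilic (L) or
Neutral (N); each backbone dihedral carries a secondary-structure class
Helix (H), Extended (E) or Turn (T).  In reduced units (energy ϵ,
distance Å, mass mu, time tu = √(mu Å²/ϵ), k_B = 1):

    V(r) = Σ_bonds k_b (r − σ)²
         + Σ_angles (k_θ/2)(θ − θ0)²
         + Σ_dihedrals A(1 + cos φ) + B(1 + cos 3φ) + C(1 + sin φ)
         + Σ_{|i−j|≥3} 4 ϵ S1 [(σ/r)¹² − S2 (σ/r)⁶]

with k_b = 115.6 ϵ Å⁻² (the bond term carries the full printed prefactor,
no ½ — the angle term does carry ½; the ½-convention for angles is not
uniquely fixed in the literature and only rescales k_θ), σ = 3.8 Å,
k_θ = 10 ϵ rad⁻², θ0 = 1.8326 rad.  Pair scalings: (B,B) → (1, 1)
(attractive), (L,L)/(L,B) → (2/3, −1) (weakly repulsive), (N,·) → (1, 0)
(excluded volume only).  Dihedral coefficients per class are a
user-editable table; the library defaults are at the
Honeycutt–Thirumalai scale, H (0, 0.2, 0.2), E (0.9, 1.2, 0),
T (0.2, 0.2, 0.2) ϵ.  The BLN parametrization is intrinsically
per-protein — the dihedral classes encode the *native* secondary
structure — so a force-field instance is always (sequence, tables).

Dynamics: velocity-Verlet with an Andersen thermostat; "collision
frequency 10⁻³" is implemented as a per-bead per-step resampling
probability at dt = 10⁻³ tu.  Global minimization: an annealing ladder
starting at T = 10 ϵ, halved ten times, 10 tu per rung, followed by
L-BFGS (RMS-force tolerance 10⁻⁶ ϵ/Å, ≤ 5·10⁴ iterations).  The minima
database repeats this from the current best guess until the best energy
is unimproved for 20 consecutive restarts, deduplicating by energy
(10⁻⁶ ϵ) and superposed RMSD (0.1 Å).

## Contact maps and the SCH metric

G_ij = 1 iff r_ij < r_c with r_c = 8 Å, strict inequality (a pair at
exactly 8 Å is not a contact).  Distances between maps:

* Hamming: number of differing unordered pairs (one bit flip = 1).
* SCH: with S the all-pairs shortest-hop matrix of the contact graph
  (BFS; disconnected pairs capped at N, which exceeds any realizable
  hop count),

      f_SCH(A,B) = 2/(N(N−1)) Σ_{i<j} |S^A_ij − S^B_ij| / max(S^A_ij, S^B_ij).

  Each summand lies in [0,1), |a−b|/max(a,b) is the relative-difference
  metric on positive integers, so f_SCH is symmetric, < 1, zero iff the
  hop matrices agree, and satisfies the triangle inequality (verified by
  a seeded property test over random map triples).  Long-range (large
  hop) differences are automatically down-weighted.

Only pairs with |i−j| ≥ 3 are mutable; nearer pairs are fixed by the
backbone (bonded neighbours at 3.8 Å are always contacts at an 8 Å
cutoff, so bead chains always yield connected contact graphs).

## Graph-driven sampling

A folding path is a graph sequence [G⁰ … G^{M+1}] with endpoints pinned
to the unfolded and folded maps.  Simulated annealing perturbs a
uniformly chosen intermediate with n_b ~ U{1..5} bit flips (without
replacement) and scores

    F = Σ_{i=1..M} |d(G^{i−1},G^i) − d(G^i,G^{i+1})|
      + λ Σ_{j=1..M+1} H(d(G^{j−1},G^j) − k_cont)

with d = f_SCH, k_cont = 0.15 (the SCH scale of one topology-preserving
step), H the Heaviside step with H(0) = 0 and λ = 1 (a single threshold
violation dominates typical equidistance residuals of ≲ 0.1).  A hinge
variant of the penalty is available behind a config switch.  Metropolis
acceptance exp(−ΔF/T) under a linearly decreasing temperature from
10⁻³ over 10⁴ updates (defaults).  Intermediates are initialized by
random linear label interpolation: intermediate i toggles a random
⌈i·K/(M+1)⌉-subset of the K mutable pairs on which the endpoints differ.
M defaults to ⌈d(G^I,G^F)/k_cont⌉ − 1.

Proposal correction is configurable: "per-update" (every flipped map is
back-mapped and replaced by the achieved map before scoring — the
literal protocol, expensive), "on-accept" (correct only accepted moves),
or "none" (pure graph-space annealing).  Ensembles in this package's own
experiments use "none" for path generation and reconstruct the final
intermediates once per path; this keeps a 100+-path ensemble tractable
on one core and leaves the stored maps self-consistent with their
conformations wherever conformations are stored.

## Back-mapping (reconstruction)

The one-sided harmonic graph restraining potential over nonbonded pairs:

    W(r,G) = Σ G_ij (k/2) max(0, r_ij − r_con)²
           + Σ (1−G_ij)(k/2) max(0, r_con − r_ij)²
           + Σ (k/2) max(0, r_steric − r_ij)²

with shared k = 100 ϵ Å⁻², r_con = 8 Å, r_steric = 2 Å; W ≥ 0 with
equality iff every restraint holds, and W is C¹ at every hinge.
Reconstruction minimizes V + W from the starting geometry, then V alone
(so the output is always a physical local minimum); the result records
the achieved map, its SCH distance to the target, and a failure flag
(non-finite output, optimizer abort, or any output pair closer than
0.5 Å).

Two numerical choices matter in practice:

* **Restraint margin.**  The bare hinge pulls a violated contact only
  until r = r_con, parking pairs exactly on the classification
  threshold, where the subsequent V-only relaxation flips them
  arbitrarily.  The back-mapping entry points therefore restrain
  contacts to r ≤ r_con − m and non-contacts to r ≥ r_con + m with
  m = 0.8 Å by default (`DEFAULT_RECONSTRUCTION_GRP`); `GRPNewConfig`
  itself defaults to m = 0 so the energy matches the plain definition.
* **Annealed retries** (optional, off by default).  Quasi-Newton descent
  on V + W cannot thread a bead past the LJ core of another, so some
  realizable targets strand in local minima of the mixed surface.  With
  `n_anneal_retries > 0` a miss is retried from configurations produced
  by short thermostatted MD on V + W (cooling ladder 1.0 → 0.03 ϵ,
  2500 steps per rung), keeping the best result by SCH distance.
* **Collapsed-angle guard.**  The harmonic angle term is finite at
  θ = 0, so V itself admits artifact minima in which an i/i+2 pair sits
  at a fraction of an Ångström (the Lennard-Jones term excludes
  |i−j| ≤ 2 by construction and cannot prevent it).  Back-mapping guards
  against this twice: the restraining potential applies a separate
  steric floor of 3.8 Å to second neighbours (`r_steric13`, zero in the
  bare `GRPNewConfig`), and the physical relaxation stage detects any
  output with a second-neighbour pair below 2 Å (or any other pair below
  0.5 Å), re-minimizes under V plus steric-only hinges, and finishes
  with a plain V minimization, so the returned structure is always a
  pure physical minimum outside the artifact basins.

The crankshaft alternative runs Metropolis MC on W: interior beads
rotate by U[−π, π] about the axis through their chain neighbours (an
exact isometry for both flanking bonds), terminal beads pivot about a
random axis through their single neighbour; any proposal creating a
nonbonded pair below r_steric is rejected outright.  Defaults: 10⁵
steps, geometric temperature decay 1.0 → 0.01, then V-minimization.
Crankshaft moves are local, so this method degrades when the target is
far from the start — the gradient method updates the whole chain at
once.

The legacy GRP (harmonic contact term + bounded logistic repulsion,
κ1 = 1 ϵ Å⁻², κ2 = 6 ϵ, γ = 6 Å², r_min = 2 Å, r_max = 8 Å, logistic
argument (r_max² − r²)/γ for dimensional consistency) is retained as a
baseline only; its exact original form is not recoverable, and the
implementation here clips the logistic argument, so its historical
failure behaviour is not reproduced.

## Path refinement

All path operations are generic over an (energy, force) contract on flat
configuration vectors, so analytic 1D surfaces exercise the same code as
the BLN binding.

* **LST** interpolation minimizes the squared deviation from linearly
  interpolated internal pairwise distances with d⁻⁴ weights plus a
  10⁻⁶-weighted Cartesian tether, seeded from Cartesian interpolation;
  non-3D vectors interpolate linearly.
* **FSM** grows frontiers alternately toward each other with LST steps
  capped at 2 Å RMSD, relaxing only the advancing image perpendicular to
  the local tangent; a frontier freezes above an RMS force of
  100 ϵ Å⁻¹; at most 10 images per side; the node string is resampled to
  10 equidistant images (RMSD arc length).
* **NEB** uses the energy-weighted upwind tangent, perpendicular true
  force plus parallel spring force (spring constant 1 ϵ Å⁻², not printed
  anywhere authoritative, config-exposed), QuickMin updates (velocity
  projected on the force direction, zeroed when antiparallel),
  convergence at per-image RMS force ≤ 10⁻⁴ and max component ≤ 10⁻²
  ϵ Å⁻¹, ≤ 10⁴ iterations.  Caveat: on a symmetric 1D double well plain
  NEB only places an image exactly at the saddle when the image count is
  odd (equal spacing); climbing-image refinement is out of scope, so the
  analytic-barrier checks use odd counts.
* **Floored energy** ΔE⁺ = Σ max(0, E_{k+1} − E_k) over the concatenated
  profile ranks paths kinetically; it is shift-invariant and zero for
  monotone descent.

## Path analysis

χ order parameters measure hairpin formation: the fraction of declared
native pairs whose distance is within a tolerance of its folded value.
The printed tolerance 0.2 is dimensionless in context; it is implemented
as an absolute default of 0.2·σ = 0.76 Å, with a relative-to-native
option.  Hairpin pair sets are the native contacts (|i−j| ≥ 3) inside
user-declared residue ranges.  Paths become (χ_β1, χ_β2) tracks —
evaluated either at the stored path conformations or, for mechanism
analysis, at the NEB images of every refined transition, which resolves
where inside the final folding step each hairpin completes — compared
with the discrete Fréchet distance (dynamic program, Euclidean point
metric) and clustered with HDBSCAN (scikit-learn, precomputed metric,
min_cluster_size = 5, noise label −1).  Clustering uses stock HDBSCAN
semantics (the hierarchy root is excluded, so a unimodal ensemble yields
clusters only where the density genuinely splits); when that labels the
entire set as noise the root is reported as a single cluster instead.
Transition segments run from the last frame with both χ < 0.4 to the
first subsequent frame with both χ > 0.8; the mechanism-clustering
experiment computes Fréchet distances on these pruned segments so that
path comparison concentrates on the transition itself rather than the
long unfolded and folded tails.

TM-score is implemented for equal-length bead chains (no alignment
search): d0(L) = 1.24(L−15)^{1/3} − 1.8 clamped below at 0.5 Å, iterative
Kabsch superposition on the d0-selected subset, score maximized over
iterations.  The metric-validation experiment builds a structurally
diverse pool — database minima plus MD-perturbed-and-minimized variants
at temperatures drawn from [0.3, 3.0] ϵ — and scores random pairs from
the pool with TM, SCH and Hamming.  Pair diversity is the crux: along a
single melt continuum from one reference both contact-map metrics track
the TM-score about equally well, but between genuinely different folds
the raw Hamming count saturates (two unrelated compact structures share
almost no exact contacts regardless of how topologically similar they
are) while the hop-based SCH distance remains graded; only the
cross-basin comparison exposes the difference the metric was designed
for.

## The synthetic test protein

`make_toy_protein` builds a 56-bead two-hairpin + helix architecture:
hairpin 1 = 9B strand / 4N turn / 9B strand, a central 12-bead
amphipathic helix (BBLN repeat), hairpin 2 = 8B / 4N / 6B, joined by
2-bead neutral loops.  `toy_protein_parameters` supplies its force-field
instance with a doubled strand/helix dihedral stiffness (H (0,0.4,0.4),
E (1.8,2.4,0), T (0.2,0.2,0.2) ϵ): with the soft library defaults the
chain collapses glassily (annealed energies near +8 ϵ, many unrelated
basins) whereas the stiffened backbone yields a cohesive, funneled
landscape (global minimum near −40 ϵ) that behaves like a genuine
two-state folder — the role the fixture exists to play.  The extended
starting chain is a planar zigzag of half-angle 0.02 rad: bonds are
exactly 3.8 Å, contacts exactly the |i−j| ≤ 2 band, and no angle or
dihedral is at its singular collinear geometry.

What the fixture does *not* emulate: real side-chain packing,
sequence-specific turn propensities, solvent, or the published bead
sequence of any real protein.  Passing tests demonstrate that the
algorithms behave as specified on a stable synthetic folder; they do not
certify accuracy for any particular real protein, and an externally
supplied sequence file is the supported route for such work.

## Problem sizes used by the shipped experiments

The test suite runs on one core: the shared minima database uses the
annealing protocol with the stop criterion shortened to 10 unimproved
restarts; the reconstruction benchmark asserts 0% failures over 100
trials per method; the physicality split uses 50 MD targets and 50
bit-flip targets (reconstruction with 8 annealed retries); the
two-mechanism experiment anneals 200 graph-space paths of 3
intermediates for 3000 updates each, reconstructs and FSM/NEB-refines
them, and clusters pruned NEB-image χ tracks; metric validation scores
200 pool pairs.  The
acceptance script (`scripts/acceptance.py`) runs the full 500-trial
benchmark for both reconstruction methods with the complete
20-unimproved-restart database protocol.

## Known limitations

* Reconstruction of *physically realizable* targets is not universally
  exact: genuinely refolded targets (high-T excursions that cross
  basins) can strand even the annealed-retry minimizer in a neighbouring
  minimum whose map differs by a few pairs.  On the canonical fixture
  roughly three quarters of T = 1.0 ϵ MD targets reconstruct to
  SCH < 0.01; bit-flip targets remain an order of magnitude farther,
  reproducing the physical/nonphysical bimodality.
* Plain NEB misses symmetric saddles for even image counts (above).
* The SA objective treats all threshold violations equally (step
  penalty); the hinge variant trades this for smoother guidance.
* HDBSCAN labels, while deterministic for fixed input, can split or
  merge mechanism clusters near the min_cluster_size boundary.
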