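# Methods

## The sampling problem

Flexible loops grafted onto rigid protein scaffolds — the antibody CDR-H3
loop is the canonical case — relax far too slowly for plain molecular
dynamics: a single wrong dihedral (e.g. a cis instead of a trans peptide
bond inherited from a homology model) can trap the simulation near its
start structure indefinitely. Solute tempering attacks this by running M
replicas at one common bath temperature T_0 while *scaling the
interactions of a selected region* ("solute") differently in each
replica, and letting the scaling parameters diffuse between replicas by
Metropolis exchanges.

## The scaled potential

Every potential term is classified against the solute selection (a set
of atoms plus the tempered categories: dihedral, vdW, electrostatic —
bond and angle terms are never tempered). A term of a tempered category
with all `l` atoms inside the solute is solute–solute (UU); with
`0 < k < l` atoms inside it is a cross term (UV); everything else is
solvent–solvent (VV). Replica at rung m with scaling parameter
β_m (solute "temperature" T_m = 1/β_m, k_B = 1) feels

    E_m(x) = (β_m/β_0) E_uu(x)
           + Σ_i (β_m/β_0)^(k_i/l_i) E_uv,i(x)
           + E_vv(x).

Setting every k_i = l_i recovers the two-bucket REST2 form; selecting
the whole system with every category recovers plain temperature
exchange. Rung swaps between neighbors (m, n = m+1), with replica a at m
and b at n, are accepted with probability min(1, e^(−Δ)) where

    Δ = (β_n − β_m)(E_uu(x_a) − E_uu(x_b))
      + Σ_i β_0^(1−k_i/l_i) (β_n^(k_i/l_i) − β_m^(k_i/l_i))
            (E_uv,i(x_a) − E_uv,i(x_b)).

E_vv cancels identically — the reason solute tempering needs far fewer
replicas than temperature exchange, whose acceptance decays with the
square root of the total degree-of-freedom count f. Both reductions and
the cancellation are asserted exactly in the test suite, and the
f^(−1/2) spacing law is recovered on harmonic baths by deterministic
quadrature.

Internally the package groups terms by their scaling exponent e = k/l,
so the sampler works with per-exponent energy components C_e(x) and
Δ = Σ_e β_0^(1−e)(β_n^e − β_m^e)(C_e(x_a) − C_e(x_b)); the per-term
decomposition of the public API is recovered from the same term tables.

## Dynamics

Two propagators are provided, both sampling exp(−β_0 E_m):

* **Langevin (BAOAB splitting)** — the default; dt = 0.005, friction
  γ = 1 in reduced units (bond stiffness 100 gives ω ≈ 10, so ~125
  steps per stiffest period). BAOAB has a small O(dt²) configurational
  bias; exactness tests therefore use the MC mode.
* **Metropolis MC** — single-particle Gaussian displacement sweeps
  (σ = 0.25 by default). For separable systems (harmonic baths) all
  coordinates are trial-moved simultaneously with per-coordinate
  acceptance, which is equivalent and fast.

Exchange sweeps alternate even pairs (1,2), (3,4), … with odd pairs
(2,3), (4,5), …, evaluated in ascending order; an accepted swap moves
the *rung assignment*, never coordinates, and since all replicas share
the bath temperature, velocities are untouched. The default exchange
period is 1000 sampler steps; short analysis-oriented runs in the tests
and the acceptance script use 50–100 steps to accumulate exchange
statistics faster (acceptance is an equilibrium property and does not
depend on the attempt period once samples decorrelate).

Randomness: one counter-based (Philox) stream per replica plus one for
the exchange controller, all spawned from a single seed, so runs are
bit-reproducible and independent of scheduling.

## Ladder optimization

Neighbor acceptance near 0.3 is the conventional sweet spot between
per-swap progress and swap frequency, and is the package default.
Starting from a ladder geometric in solute temperature (ceiling
5·T_0 by default — only an initialization; the optimizer moves it),
each round runs a short trial, measures per-pair acceptance p_m, and
rescales the log-temperature gaps:

    ln(T_{m+1}/T_m) ← ln(T_{m+1}/T_m) · (ln target / ln p_m)^0.6

with p_m clipped to [0.005, 0.995] and the factor clamped to
[0.45, 2.2]. The exponent 0.6 damps oscillations driven by the trial's
own binomial noise (≈ 0.03 at 200 attempts per pair); rounds are
warm-started from the previous round's coordinates. The optimizer
returns the best ladder observed (smallest worst-pair deviation), with a
convergence flag and a warning — not an error — on non-convergence,
since with finite trials the all-pairs-within-tolerance event is partly
luck even at a perfect ladder. β_1 = β_0 is never modified.

## Fixtures and what they emulate

**Harmonic baths** (f independent 1D oscillators, the first f_u of them
solute) make everything analytic: tempered energies are
Gamma(f/2, 1/β) distributed, so pair acceptance is a deterministic
quadrature (`pair_acceptance_gamma`), fixed-acceptance spacing is a
root-find on it, and the β_1 marginal is an exact Gaussian for KS
testing. They emulate the *scaling structure* of solvated systems, not
their anharmonicity.

**The mini-loop** emulates a CDR-like loop: a macrocycle of beads whose
framework arc is positionally restrained (the rigid domain) and whose
loop segment bridges the gap with slack, carrying one bistable dihedral

    U(φ) = (barrier/2)(1 + cos(2φ − π)) + (tilt/2)(1 + cos φ)

with wells at φ ≈ 0 (cis — the emulated homology-modeling error, the
start structure) and φ ≈ π (trans — the reference structure, favored by
the tilt as the trans peptide bond is in proteins). Defaults: 12
framework beads, 16 loop beads, barrier 14, tilt 8, harmonic bonds
(k = 100, r_0 = 1) and angles (k = 20), soft extended-state dihedrals
(K = 1) along the loop, Lennard-Jones ε = 3, σ = 1.2, alternating ±1
charges, and an untempered flat-bottom spherical well ("corral",
k = 25, R = 2.2) around the gap region.

Two of these choices deserve justification. First, the loop is a
*macrocycle* and sits in a *corral*: in real solvated systems the
tempered solute stays immersed in its environment at every rung, so its
tempered interaction energy keeps fluctuating; a dangling bead chain
instead evaporates away from everything once hot, its tempered energy
stops fluctuating, and no ladder — however wide — can push neighbor
acceptance down to 0.3. Anchoring both ends (as a CDR loop is anchored)
and confining the loop region (solvent crowding) keeps the tempered
heat capacity alive across the whole rung range. Second, the sizes and
energy scales (16 loop beads, ε = 3, q = ±1) were chosen so the
tempered region carries enough heat capacity (~25 k_B near T_0) that an
8-rung ladder can realize ≈ 0.3 everywhere while conventional sampling
at T_0 remains trapped: with barrier 14 the unbiased cis→trans rate is
zero over 10^5-step runs, while dihedral-tempered gREST crosses tens of
times in the same β_1 budget. The tilt of 8 makes trans (the
"experimental" state) both the potential-energy and the free-energy
favorite of the β_1 ensemble — so low energy correlates with low RMSD
to the reference — while cis is still visited, giving the two-state
behavior the analysis layer is meant to resolve.

What the fixture does *not* emulate: explicit solvent and its
dielectric screening, realistic amino-acid force fields, PME
electrostatics, constraint algorithms, or the entropic complexity of a
21-residue loop. Passing tests show the algorithmic machinery —
classification, scaled potentials, exchange criterion, ladder logic,
sorting, analysis — is correct at desk scale, not that any particular
nanobody result is reproduced.

**Discrete systems** carry explicit per-state (E_uu, E_uv,i, E_vv)
tuples so the full extended-ensemble transition matrix of one
propagation + exchange round can be enumerated and its stationary law
compared with the product of scaled Boltzmann weights (total variation
≤ 1e-8 in the tests) — the detailed-balance proof the continuous
samplers cannot give exactly.

## Analysis conventions

* Sorting assigns the frame of replica a at time t to the rung it held
  while being propagated (frames are saved just before the exchange
  attempt at their own step). The β_1 stream is the physical ensemble.
* RMSD uses Kabsch superposition (SVD with determinant correction); the
  fit selection and the measured selection are independent arguments
  because the underlying protocol is ambiguous about superposing on the
  framework versus the loop — the default ties them together.
* Distance-matrix PCA uses the flattened upper triangle of the pairwise
  Cα distance matrix, mean-centered; it is superposition-free by
  construction. Eigenvector signs are fixed by making each component's
  largest-magnitude loading positive. Eigenvalues use ddof = 1.
* The energy–structure diagnostic reports Pearson correlation between
  per-frame RMSD and the scaled total energy E_m at β_1.
* Round trips are counted per replica as completed β_1 → β_M → β_1
  traversals of the rung ladder.

## Numerical notes and limitations

* Reduced units throughout (k_B = 1); nonbonded interactions are plain
  non-periodic, cutoff-free LJ 12-6 (Lorentz–Berthelot) and Coulomb;
  1-2/1-3 pairs excluded, 1-4 at full strength.
* The angle force uses a clamped sin θ (θ_0 defaults stay well away
  from collinearity); dihedrals use the IUPAC sign convention; all
  forces are validated against central differences at 1e-6.
* The numba kernels are an exact reimplementation of the numpy
  reference path (cross-checked to ~1e-12 in the tests); either path
  can be selected on a compiled model.
* Exchange with MC propagation satisfies detailed balance exactly;
  with BAOAB it inherits the integrator's O(dt²) bias.
* Energies can overflow to +inf for overlapping LJ cores in MC trial
  moves; such moves are rejected. The Langevin integrator instead
  raises on non-finite coordinates.
* Problem sizes in the tests and the acceptance script (10^5–2·10^5
  sampler steps, 8 replicas, 28 beads) are chosen as comfortable
  desk-scale runs; all stochastic assertions carry explicit sampling
  error bands derived from their own statistics.
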