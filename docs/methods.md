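# Methods

This note records the models behind `pesmap`, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## The basin-hopping loop

Basin-hopping transforms a potential energy surface into the staircase of
its local minima: perturb → screen → minimise → accept. Two acceptance
criteria operate side by side:

* **definite replacement** — a minimised candidate below the lowest energy
  found so far (E_low) is always adopted;
* **conditional acceptance** — otherwise the walk moves with Metropolis
  probability min(1, e^(−(E_new − E_current)/kT)). `thermal_energy` is the
  k_B·T of this window, in the potential model's own energy units; larger
  values tolerate larger uphill moves and de-trap the walk at the cost of
  less focused sampling.

Every *converged* minimum encountered is offered to the library whether or
not the walk adopts it: the library is the map of the surface, and E_low is
defined over everything identified, not everything accepted. Steps rejected
by screening still consume the step budget and are logged with the violated
rule, so `n_steps` is an honest cost measure.

Moves are resolved from the model's topology: each rotatable dihedral is
twisted uniformly within ±`dihedral_step` (default 5°), each designated
moiety rotated rigidly within ±`rigid_rot_step` per body axis (default 5°)
and translated within ±`translation_step` per Cartesian direction (default
0.5 Å). For atomic clusters every atom is its own moiety, which reduces to
the classic per-atom displacement move. Dihedral and rigid moves preserve
bonded distances by construction.

Screening rejects candidates with any non-bonded pair closer than
`min_interatomic` (default 0.8 Å; bonded pairs are exempt) or any atom
farther than `interaction_radius` (default 15 Å) from the centre of mass —
the standard clash and dissociation guards. Both are config-exposed because
sensible values are system- and unit-dependent (the Lennard-Jones studies
use 0.5 σ and 6 σ).

## Uniqueness of minima

Two records describe the *same* minimum only when they are jointly
energy-near (|ΔE| < `energy_tol`, default 1e-5) **and** geometry-near
(distance-matrix similarity < `similarity_tol`, default 50 Å, appropriate
for a ~28-atom organic dimer). A candidate distinct in either sense is
registered. Because the distance-matrix index is reflection-invariant,
enantiomeric minima (identical energy, identical distance matrix) are
deliberately counted once.

The distance-matrix index is the raw pair sum Σ_{i<j}|ΔD_ij|, not a per-pair
mean: thresholds therefore scale with atom count, and the defaults assume
the ~28-atom scale. The LJ₁₃ studies scale them by pair count
(378 → 78 pairs) to ΔE ≥ 1e-5 ε OR d ≥ 10 σ.

### Atom mapping

The distance matrix is not permutation-invariant, so before comparison the
labelling of one structure is adjusted to (approximately) minimise the
index. Exact minimisation is a hard combinatorial problem; the
`mapping="element"` policy solves one linear assignment per element with
|R_i(A) − R_j(B)| (mass-weighted centre-of-mass distances) as cost, then
runs a pairwise-swap (2-opt) descent on the actual index. The swap
refinement matters for symmetric clusters — in an icosahedral shell all
vertices tie in centre-of-mass distance, and assignment alone returns an
arbitrary vertex permutation. The mapped index is floored at the identity
labelling's value, so the policy never does worse than not mapping. On
random ≤6-atom structures the heuristic sits within 5% of the exhaustive
optimum (asserted in tests); no optimality guarantee exists in general.

The cosine metric's convention: atom identity tracked through a run →
unsorted vectors (`sorted=False`, the default); structures of different
provenance → `sorted=True`, which buys permutational invariance for
low-symmetry species at some discriminating power.

Atomic masses are most-abundant-isotope values at 4-decimal precision; the
pseudo-element "X" (mass 1) serves reduced-unit model particles.

## Local minimisation

Quasi-Newton (L-BFGS-B) with analytic gradients, gradient max-norm
tolerance 1e-6 (model units/Å), 2000 iterations. The function-reduction
criterion is disabled so the gradient criterion governs; when the optimiser
nevertheless halts on round-off above the tolerance it is restarted from the
iterate with fresh curvature memory (up to three attempts), which in
practice always finishes the descent. `converged` is re-verified from the
returned geometry's gradient, never trusted from optimiser status. A
non-finite energy mid-search raises a divergence error carrying the last
finite iterate.

## Model potentials

* **Lennard-Jones**: pairwise 4ε[(σ/r)¹² − (σ/r)⁶], reduced units ε = σ = 1
  (the global-optimisation benchmarking standard). Near-coincident atoms
  (r < 1e-8 σ) raise rather than overflow.
* **Torsional chain**: atoms i—i+1 bonded at unit length, tetrahedral
  angles; conformational energy is a cosine series Σ k(1 + cos(nφ − φ₀))
  per dihedral plus soft-sphere repulsion k_rep(r_rep/r)¹² between atoms
  more than three bonds apart. Stiff harmonic bond (k = 100) and angle
  (k = 50) restraints — zero at the ideal chain geometry — are included so
  Cartesian minimisation has restoring forces; they do not move the
  torsional minima. The conformational search therefore effectively happens
  in dihedral space, mirroring searches that fix bonded distances.
* **Artificial interpolation force field**:
  V = χ·Σ_{i<j} (D_C,ij − r̄_ij)²/r̄_ij with
  r̄ = λ·D_A + (1−λ)·D_B — harmonic terms whose force constants fall off
  with the target distance. χ defaults to 1 (it only scales the
  optimisation). A distance matrix determines a structure only up to
  reflection; both mirror realisations are accepted as valid interpolants.

All gradients are validated against central finite differences (1e-5
relative) in the test suite.

## Interpolation

Stage 1 minimises the artificial force field from a Kabsch-aligned Cartesian
blend λ·A + (1−λ)·B (jittered by 0.01 Å if the blend degenerates into
near-coincident atoms); stage 2 re-minimises under the real model. For a
3-atom system any convex blend of two valid distance matrices is exactly
realisable (triangle inequalities survive convex combination), so stage-1
residuals vanish; for larger systems r̄ is generally not embeddable in 3-D
and the stage-1 structure is the least-squares compromise, which is all a
guess structure needs to be. An ideal interpolant at factor λ satisfies
d(A,C) = (1−λ)·d(A,B) and d(B,C) = λ·d(A,B); `verify_ratio` reports the
deviations from this proportionality, which shrink as the endpoints
approach.

The constrained Monte Carlo alternative reuses the BH loop with an extra
acceptance rule, d(·,A) ≤ r_A and d(·,B) ≤ r_B, confining sampling to an
ellipsoid-like region between the endpoints; radii below half the endpoint
separation are rejected as infeasible. Interpolants are registered against
the existing library with the same uniqueness thresholds as the search
itself.

λ defaults to 0.5 — the midpoint is the natural transition-state guess and
the hardest interpolation to reach by perturbing either endpoint.

## Clustering and embedding

WPGMA is implemented directly (the merge rule is a one-line average and the
determinism of the nearest-pair tie rule — lowest lexicographic cluster-id
pair — is part of the contract); it is cross-checked in tests against both a
literal recursion oracle and scipy's `weighted` linkage. Ward linkage uses
scipy's Lance–Williams implementation applied to the raw similarity matrix.
The similarity indices are not exactly Euclidean, which Ward formally
assumes; the linkage is applied regardless, trading geometric rigour for
variance-based grouping — acceptable for the qualitative "which minima
belong together" question it answers.

MDS: classical (eigendecomposition) initialisation refined by SMACOF stress
majorisation (scikit-learn), fixed seed. The reported stress is recomputed
from the returned coordinates — Σ_{i<j}(‖x_i − x_j‖ − M_ij)² — so it is
self-consistent by construction.

## Spectral pipeline

Lorentzian convention: each stick contributes intensity·γ²/((ν−ν_k)²+γ²),
i.e. unit peak height scaled by the stick intensity, γ = FWHM/2. Since every
region is subsequently max-normalised to 1, only relative shape matters and
the peak-height/unit-area choice is immaterial; peak-height is the simpler.
Defaults: 15 cm⁻¹ FWHM, 2 cm⁻¹ grid, regions 1000–1900 cm⁻¹ (scale 0.9679)
and 3200–3800 cm⁻¹ (scale 0.95) — empirical harmonic scalings for
fingerprint and X–H-stretch windows. Region assignment of a stick is by its
unscaled frequency; out-of-region sticks are dropped with a warning.
Computed spectra are linearly resampled onto the experiment's grid before
the Euclidean comparison. Digitisation of published figures is out of
scope; the experiment enters as a two-column table.

The scaled similarity 1 − (d − d_min)/max(d − d_min) pins the best isomer at
exactly 1 and the worst at exactly 0, and is invariant under affine
rescaling of the distances. It is a *relative* ranking — it says nothing
absolute about match quality, and a degenerate set (all distances equal) is
an error, not a score.

## Ensemble mobility

Gibbs energies are molar (kJ·mol⁻¹), so populations use the gas constant R:
f_i(T) ∝ e^(−ΔG_rel,i·1000/RT), normalised to sum to 1 (the only convention
under which Ω_B(T) = Σ f_i·Ω_i is a true average and stays within the
ensemble's CCS bounds). Tabulated ΔG(T) interpolates linearly and refuses to
extrapolate; analytic conformers use ΔG = ΔH − T·ΔS/1000. Two analytic
conformers cross at T = 1000·ΔΔH/ΔΔS, where their populations are equal.
The default temperature grid is 300–800 K in 10 K steps — the effective-
temperature range an ion sweeps during a differential-mobility duty cycle.

The projection-approximation CCS is the orientation-averaged projected area
of the union of atom-centred disks (van der Waals radius + 1.55 Å N₂ probe
radius, both config-exposed), Monte Carlo estimated with seeded rotations
and sample points, reported with the standard error over orientations. It
is a hard-sphere geometric estimate: no long-range ion–neutral potential,
no scattering physics, and it systematically undershoots trajectory-method
CCS values for large ions. It serves ensemble *trends* (relative conformer
sizes, Ω_B(T) shape), not absolute instrument comparison.

## Synthetic generators and what passing tests mean

All generators are pure functions of (parameters, seed):

* `make_lj_cluster` — uniform placement in a box of edge 1.3·n^⅓ σ with a
  0.7 σ minimum separation: a realistic condensed random start for BH.
* `make_torsion_chain` — unit bonds, tetrahedral angles, chosen or random
  dihedrals (NeRF construction).
* `make_difluoroethene_like` — idealised sp² geometries (C=C 1.33 Å, C–F
  1.35 Å, C–H 1.09 Å, 120° angles) of the three difluoroethene isomers,
  adequate for qualitative clustering structure (the 1,2-isomers pair up
  before joining the 1,1-isomer), not for reproducing quantum-chemically
  optimised similarity values.
* `make_spectra_set` — random sticks per region with one designated carrier
  whose processed spectrum, multiplied by (1 + noise·N(0,1)) and
  re-normalised per region, becomes the "experiment". Default 10 isomers,
  ~7 lines per region, 5% noise.
* `make_two_state_ensemble` — compact (Ω = 148 Å², ΔG ≡ 0) vs extended
  (Ω = 160 Å², ΔH = 10 kJ·mol⁻¹, ΔS = 25 J·mol⁻¹·K⁻¹ → crossover at exactly
  400 K): an analytically solvable cartoon of entropy-driven unfolding.

What these do **not** emulate: quantum-chemical energetics and frequencies,
anharmonicity, experimental IRMPD intensity physics (fragmentation-channel
coupling), real conformer thermochemistry, or buffer-gas interaction
physics. A passing suite demonstrates the machinery — search, deduplication,
clustering, interpolation, ranking, weighting — is correct on surfaces and
spectra whose ground truth is known by construction; it does not certify
accuracy for any particular chemical system, which is set by the potential
and spectra you feed in.

## Scaled-down benchmark conditions

The LJ₁₃ augmentation study (`pesmap.benchmarks`) uses: kT = 0.8 ε (the
canonical LJ basin-hopping temperature), 500 steps per run, 8 parallel
seeded runs, uniqueness ΔE ≥ 1e-5 ε OR d ≥ 10 σ with element-constrained
mapping, interpolation candidacy d > 15 σ (1.5× the uniqueness threshold,
admitting roughly the distant half of library pairs) capped at 50 pairs,
λ = 0.5. Success is judged against an independent 500-start local-
minimisation oracle (which reliably finds the −44.3268 ε icosahedron).
These sizes keep a full study around two minutes on one CPU while leaving
the qualitative conclusions — interpolation enlarges the library and never
worsens the best energy — comfortably reproducible across seeds.

## Known limitations

* BH is stochastic; no run guarantees the global minimum. Confidence comes
  from consistency across seeds and the oracle cross-check.
* The atom-mapping heuristic can overestimate similarity distances for
  highly symmetric structures despite the 2-opt refinement; the joint
  energy+geometry uniqueness test makes the failure mode a rare duplicate
  entry, not a lost minimum.
* The mass-weighted vector cannot distinguish conformations that agree in
  all centre-of-mass distances (e.g. square-planar vs tetrahedral AB₄ at
  equal bond lengths); prefer the distance matrix when symmetry is high.
* Structures with different atom counts are not comparable; compositions
  must match exactly.
* Ward-on-non-Euclidean-distances and the PA cross section are deliberate
  approximations, as discussed above.
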