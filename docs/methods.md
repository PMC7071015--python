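# Methods

This note documents the models and numerical choices behind cyclomimic:
what is computed, under which assumptions, with which defaults, and what
the synthetic-data validation does and does not demonstrate.

## Molecular representation

Peptides are reduced to a per-residue atom set: backbone N, (amide H),
CA, HA, C, O, a CB carbon for every non-glycine residue, and — for side
chains extending past CB — a single pseudo-atom `SC` at a residue-specific
distance from CB standing in for the distal side-chain centroid (1.2 Å
for Val up to 3.6 Å for Arg; coarse averages, not rotamer-accurate).
Proline keeps no amide proton; glycine carries one HA.  The proton sites
available to NOE restraints are the amide HN, the alpha HA, and a beta
pseudo-proton HB that shares the CB position; restraints to HB receive the
standard +1.0 Å pseudo-atom allowance on their upper bound.  This
representation covers the distance classes that backbone-defining NOEs
probe (HN–HN, HN–HA, HA–HA, and beta contacts) while keeping the energy
model small enough for dense sampling.

Ideal geometry follows rounded Engh/Huber values (N–CA 1.458, CA–C 1.525,
C–N 1.329, C=O 1.231, CA–CB 1.530 Å; backbone angles 111.0/116.6/121.7°).
Three CA-centred angle ideals (C-CA-CB 108.16°, C-CA-HA 108.69°,
CB-CA-HA 108.94°) are the values implied by the ±120° branch construction
around the N–CA axis, so a freshly built structure is exactly at its
angle ideals.  L-configuration at CA is maintained by a restraint on the
unit-vector triple product s = (û_N × û_C)·û_CB with target 0.766, the
value of ideal L-amino-acid geometry.

Coordinates are realised from internal coordinates by natural-extension
(NeRF) placement.  For cyclic designs the backbone torsions (and, with a
stiff penalty, the omega angles) are refined by L-BFGS until the ring-
closure C–N distance is within 0.05 Å of the ideal peptide bond (hard
failure above 0.3 Å).  Omega flexibility matters only for very small
rings: an all-trans cyclic tetrapeptide cannot close with rigid planar
peptide bonds (residual gap 0.38 Å), matching the real strain of
tetrapeptide macrocycles; the 11-mer closes with planar bonds.

## Energy model

A transparent geometric potential, not a physical force field — absolute
energies rank conformations and drive sampling; they are not comparable
to thermochemical data:

| term       | form                                   | default constant |
|------------|----------------------------------------|------------------|
| bond       | k (d − d₀)²                            | 2500 kJ/mol/Å²   |
| angle      | k (θ − θ₀)²                            | 150 kJ/mol/rad²  |
| torsion    | k (1 + cos 3φ) on phi/psi              | 0.3 kJ/mol       |
| repulsion  | k (d₀ − d)² for d < d₀, heavy atoms    | 400 kJ/mol/Å², d₀ = 2.6 Å (×0.7 for 1-4 pairs) |
| omega      | k (1 − cos(ω − ω₀)), ω₀ = π (trans) or 0 (cis) | 50 kJ/mol |
| chirality  | k (s − s₀)², s₀ = 0.766                | 200 kJ/mol       |
| closure    | bond/angle/omega terms of the ring-closure bond | 2500 kJ/mol/Å² |
| NOE        | flat-bottom: zero in [lower, upper], harmonic outside | 50 kJ/mol/Å² |

Hydrogens are excluded from the soft-sphere term (their positions are
determined by the heavy-atom frame; the 1.8 Å hard-sphere clamp on
restraint lower bounds protects proton contacts).  Every term has an
analytic Cartesian gradient; the test suite validates the gradients
against central finite differences and the numba-compiled kernels against
the pure-numpy implementation to machine precision.  Energies are
reported in kJ/mol; the gas constant is 8.314 × 10⁻³ kJ mol⁻¹ K⁻¹, so
exp(−E/RT) is dimensionless with E in kJ/mol.

Minimisation is L-BFGS-B with the analytic gradient, run to tight
internal convergence and verified against the requested RMS-gradient
tolerance (default 0.01 kJ/mol/Å, the conventional truncated-Newton
setting for this workflow); an unconverged result is returned flagged,
never silently.  Minimisation never returns a higher energy than its
input.

## Conformational search

Basin hopping: every atom is displaced by an independent random vector
uniform in the ball of radius `max_displacement` (default 3 Å), the
perturbed structure is minimised, and the move is accepted by the
Metropolis criterion on minimised energies at the search temperature
(default 500 K, 5000 steps).  Distinct accepted minima (energy gap
> 10⁻⁶ kJ/mol) form the ensemble; structural duplicates are merged
afterwards by all-atom superposed RMSD with the lower-energy member kept.
Boltzmann factors are computed after shifting energies by the ensemble
minimum (overflow-safe, ratio-preserving) and ratios are referenced to
the highest-energy member, so every reported ratio is ≥ 1.

An exhaustive torsion-grid scan (`torsion_grid_scan`) provides an
independent reference on small systems: on a 4-residue toy macrocycle the
30°-grid over the four phi angles (psi held at the closure-refined
extended values; 20 736 grid points, best point then minimised) bounds
what the stochastic search must reach.  A full grid over all eight
torsions (4.3 × 10⁸ points) is not feasible at desk scale, so the scan is
exhaustive over the phi manifold and the comparison is one-sided: the
search must find an energy no worse than the grid reference.

## NOE calibration

r_ij = r_ref (α_ref / α_ij)^(1/6) applied peak by peak; bounds are
r_ij ± 0.5 Å with the lower bound clamped to the 1.8 Å hard-sphere
contact (and never above r_ij itself), +1.0 Å on the upper bound per beta
pseudo-proton in the pair.  Calibration is scale-invariant in the volume
units and exactly inverts the forward model α = c·r⁻⁶.  The calibration
reference pair in synthetic spectra is the intra-residue HA–HB pair of
the first residue carrying both: the two sites live in the rigid frame of
CA, so their separation is fixed by construction (~2.1 Å) — the
"known distance" a real experiment would take from a geminal pair.

Proline cis/trans classification uses the ¹³C Cβ–Cγ shift difference:
Δδ ≤ 6.0 ppm → trans, Δδ ≥ 8.0 ppm → cis, ambiguous between (the
established convention: ~4.5 ppm typical trans, ~9.15 ppm typical cis).
The classified configuration enters the builder and the omega term's
target, enforcing the configuration throughout annealing.

## Restrained annealing protocol

Each run has three phases, all driven by one seeded RNG:

1. **Cooling** — Metropolis annealing in torsion space (phi/psi/chi; one
   torsion per move, Gaussian step of width max(0.05, 1.2√(T/T_start))
   rad) from 3500 K to 100 K, geometric by default, 60 000 steps
   (10 000 at the reduced desk scale used by the tests and the
   acceptance script).  The NOE constant ramps 2 → 50 kJ/mol/Å² per the
   schedule; the ring-closure and soft-sphere constants ramp from soft
   (10 and 1) to full stiffness so that early moves can pass the closure
   barrier — torsion moves on a closed ring otherwise face enormous
   closure penalties and the chain cannot rearrange.
2. **Refinement** — basin hopping (default 50 iterations; 1–2 torsion
   perturbations of width 0.25 rad, short minimisations, Metropolis at
   150 K) against *centre-tightened* restraints: flat bottoms collapsed
   to r_ij ± 0.05 Å at 100 kJ/mol/Å².  Wide flat bottoms make the
   restrained energy landscape degenerate — minima sit anywhere inside
   the feasible set and get frustrated at bound edges; pulling distances
   toward their calibrated targets removes the degeneracy and funnels
   runs into the globally consistent fold.  Without this stage no run at
   desk scale reached exact 100 % bound satisfaction.
3. **Final minimisation** — under the original flat-bottom bounds at the
   schedule's end constant.  All violation reporting uses the original
   calibrated bounds, never the tightened ones.  The protocol also never
   returns a structure with higher restrained energy than plain
   minimisation of its starting structure would give.

Ensembles are n independent runs (default 10, matching the reported
7 + 3 converged structures of the motivating study design) from random
closure-refined starts, sorted by restrained energy, each carrying its
violation report.  A restraint is counted satisfied when its flat-bottom
violation is zero (≤ 10⁻⁹ Å numerically).

## Ensemble analysis

Superposition is the closed-form SVD solution with the determinant guard
against reflections; "backbone" means N, CA, C (carbonyl O excluded —
the main-chain convention adopted here).  Clustering is average-linkage
hierarchical clustering (scipy) on the pairwise backbone-RMSD matrix,
cut at 2.0 Å by default; clusters are ordered by size, ties broken by
lowest member energy.  The cyclic-to-reference mapping is by residue
identity of the epitope segment (macrocycle residues 1–9 onto loop
residues 1–9; linker excluded); rotational re-registration of the cycle
is not attempted by default.  The mimicry table ranks labelled structures
by ascending backbone RMSD to the reference; unmappable structures are
flagged, never dropped.

## Dose-response analysis

%inhibition = 100 (A_neg − A) / (A_neg − A_baseline), with the
neutralising-antibody positive control preferred as the 100 % anchor and
the vehicle blank used when no positive control exists; zero dynamic
range is a hard error.  The 4PL is fitted by least squares on per-well
points (replicate scatter informs the standard errors) with IC₅₀
parametrised on the log scale and the Hill slope unconstrained in sign
so agonist-shaped data fail loudly.  Because the responses are already
normalised to the plate controls, the asymptotes are fixed at 0 and
100 % by default (the standard normalised-response model): estimating
bottom and top from eight duplicated doses roughly doubles the IC₅₀
error (median ~11 % versus ~4.5 % at 5-point noise in our simulations)
while adding no information the controls do not already carry.  A
bounded-free four-parameter fit (bottom/top in [−20, 120] %) remains
available via `constrain_asymptotes=False` for un-normalised or
atypical data.  Initial guesses come from the data anchors and the
half-response crossing, making the fit deterministic and row-order
invariant.  An IC₅₀ outside the tested dose range sets the
`extrapolated` flag.

## Synthetic data and what recovery shows

Ground truths are compact, clash-free, ring-closed conformations from
unrestrained annealing (1500 → 100 K, 5000 steps) of random starts.
NOESY volumes are α = c·r⁻⁶ for every proton-site pair within 5 Å, with
multiplicative log-normal noise (volumes are positive and errors roughly
proportional); an optional subsampling fraction thins the peak list to
the ~27-restraint scale typical of a real 11-mer data set.  Plates invert
the normalisation formula from 4PL %inhibition with additive Gaussian
noise in percentage points on the dose wells; control wells report their
true levels, since a real plate pins the normalisation anchors by
averaging a full control column and a two-well noisy anchor would by
itself dominate the IC₅₀ error budget.

Noise-free recovery (10 runs, 10 000-step schedule) reaches best backbone
RMSD ≈ 10⁻³ Å with 100 % restraint satisfaction; at σ = 0.1 volume noise
the median best RMSD over five independent truths stays far below 1 Å —
the r⁻⁶ law compresses 10 % volume noise into ~1.7 % distance noise,
well inside the ±0.5 Å bounds.  These experiments validate the
*machinery* (forward model inverted, sampler reaches the consistent
basin, every stage deterministic under seed).  They do not demonstrate
performance on real spectra: synthetic volumes have no spin diffusion,
overlap, or integration error; the reduced proton set is far denser in
information than 27 hand-assigned NOEs; and the geometric potential has
no electrostatics or solvation, so real conformational preferences
(e.g. solvent-dependent turns) are outside its scope.

## Problem sizes and numerical details

Tests and the acceptance script run the annealing at 10 000 cooling steps
with 100 refinement iterations (15 for the noisy replicates, whose
recovery margin is wide), 10 runs per ensemble, 5 truths for the noisy
median, 20 736-point torsion grids, 50 superposition trials and 100
plate simulations — sizes chosen so the
full validation completes in minutes while leaving wide margins on every
recovery criterion.  The rotation-grid superposition reference is
hierarchical (6° full Euler grid, then an exhaustive 1° neighbourhood),
equivalent in resolution to a flat 1° grid at a millionth of the cost.
All randomness flows through `numpy.random.default_rng` seeds recorded in
reports; identical seeds replay bitwise-identical results.

## Known limitations

- The potential is geometric: no electrostatics, hydrogen bonds,
  Lennard-Jones attraction or solvent; energies are internal units.
- Side chains beyond CB are single centroids; chi sampling is one angle.
- The annealer is Metropolis in torsion space, not Cartesian dynamics;
  temperature is an acceptance parameter, not a kinetic one.
- Cis/trans classification thresholds are conventions, and the ambiguous
  band (6–8 ppm) is reported as such rather than guessed.
- Mimicry ranking assumes the epitope residues map 1:1 onto the
  reference loop; no sequence alignment is attempted.
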