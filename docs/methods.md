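# Methods

`stiffnet` measures how rigidly pairs of residues move relative to one
another in conformational ensembles of proteins, and uses that signal to
derive distance- and amino-acid-pair-specific spring constants for elastic
network models (ENMs).  This note records the model, the estimation
procedure, the numerical choices, and what the synthetic benchmarks do and
do not establish.

## The elastic network model

A protein of N residues is reduced to one bead per residue at the Cα
position.  Beads interact through Hookean pair potentials

    V = Σ_{i<j} ½ k_ij (d_ij − d⁰_ij)²,

with the input structure defining the equilibrium distances d⁰_ij, i.e. the
global energy minimum.  Classic variants set k as a function of distance
only, k(d) = γ (d/1 Å)^(−p) Θ(r_c − d); the presets are `enm10` (r_c = 10 Å,
p = 0), `enm13` (13 Å, 0), `pfenm` (no cutoff, p = 2) and `pow6` (no cutoff,
p = 6).  Table-driven variants look k up in a derived table keyed by the
unordered amino-acid pair and a 0.5 Å distance bin.  Covalently bonded
(consecutive) residues always receive a stiffer spring: 10 times the mean
non-bonded spring constant at 3.5 Å separation, averaged over amino-acid
types.

Equilibrium statistics come from the 3N × 3N Hessian H of V.  Its
pseudo-inverse over the non-rigid-body modes, scaled by kBT, is the
coordinate covariance C; the predicted mean-square residue fluctuation
(MSRF) of residue i is the trace of the 3 × 3 diagonal block C_ii, related
to the crystallographic B-factor by B = (8π²/3)·MSRF.  Eigenvalues below
1e-8 of the largest count as rigid-body modes; a connected, non-collinear
network must have exactly six (five for collinear geometries such as an
isolated bead pair), and more indicates a disconnected or mechanically
degenerate network, which is an error rather than a warning because every
downstream quantity would silently absorb the spurious compliance.

Spring constants are defined up to one multiplicative constant (the
temperature).  That constant is fitted per protein by matching the sums of
predicted and observed MSRF, so every reported metric is invariant to the
global scale of a spring model.

## Apparent stiffness and the mean protein environment

For a residue pair (i, j) with distance variance σ² over an equilibrium
ensemble, the apparent stiffness is k_app = kBT/σ².  It is an *effective*
rigidity: the whole network contributes, so two pairs with identical direct
springs can differ several-fold (the 8-bead toy in `simulate.make_braced_pair_toy`
demonstrates this, together with the fact that pairs sharing no spring at
all still have finite k_app).  The uncorrelated variant k_unc recomputes σ²
after zeroing every cross-covariance block C_ij (i ≠ j), isolating what the
two residues' individual anisotropic fluctuations alone would predict.

Experimental variances come straight from the per-model distances (population
normalisation).  Model variances come from first-order propagation,
σ² = J C_pair Jᵀ, with J = (u, −u) the distance Jacobian evaluated at the
mean (experimental side) or representative (model side) coordinates.  The
approximation drops the curvature of the distance function; it is accurate
to a few percent while fluctuations stay small against the separation
(protein-like B-factors), but degrades for stiff-along/floppy-transverse
pairs — bonded neighbours at wagging chain termini are the canonical case,
and sub-protein-sized toys with soft collective bending modes can violate
it badly.  All scientific uses here (profiles, derivation, ε_σ) dismiss
bonded pairs, which keeps the propagation inside its domain of validity;
the Monte-Carlo and Langevin cross-checks in the test suite quantify this
on compact fixtures.

Pooling pairs over many proteins gives the stiffness of a *mean protein
environment*: per (amino-acid pair type, distance bin) cell, variances are
averaged with each pair weighted by its protein's model count n_p, and
k_app = kBT/⟨σ²⟩.  Averaging variances rather than stiffnesses keeps single
near-rigid pairs from dominating a cell (an alternative harmonic pooling
was evaluated and destabilises the derivation).  Bins are half-open, 0.5 Å
wide, with edges on multiples of 0.5 Å — fine enough to resolve the
5–5.5 Å hydrogen-bonding feature of secondary structure.  Pairs are binned
by their ensemble-mean distance, the natural estimator of the equilibrium
distance: its standard error shrinks with the model count, whereas any
single model's distances carry the full thermal spread and systematically
contaminate bins adjacent to sharp features of k(d).

Sparse pair types are blended toward the type-agnostic (ALL) profile with a
pseudo-count N₀ = 500: ⟨σ²⟩_blend = (N_aa⟨σ²⟩_aa + N₀⟨σ²⟩_ALL)/(N_aa + N₀),
where N_aa = Σ_p n_p N_{p,aa} is the weighted occurrence count.  The same
threshold serves as an evidence floor for whole bins: a bin whose ALL-row
count is below N₀ cannot anchor a confrontation at all and is treated as
unobserved (see below).  N₀ is interpretable as the number of occurrences
needed for a relevant estimate; values far smaller admit aberrant cells,
far larger erase sequence specificity.

## Ensemble preprocessing

Multi-model PDB files are reduced to Cα traces of one chain (chain A when
present).  Models must agree in residue count and labels.  Superposition
iteratively fits every model to the evolving mean structure (Kabsch, unit
weights) until the mean moves less than 1e-9 Å RMS, which makes the
operation idempotent to below 1e-8 Å.  The representative model is the one
closest to the mean (RMSD, ties to the lowest index).  Unfolded termini are
trimmed by a single pass of the rule "MSRF above twice the protein mean",
applied only to maximal terminal runs; the mean is not recomputed after
removal.  Validation requires at least 20 models, at least 50 residues, and
no consecutive-residue Cα–Cα distance above 4.5 Å in the representative
model (3.8 Å is the trans peptide spacing; 4.5 Å tolerates cis peptides and
strain).

## Iterative derivation of effective potentials

The derived tables make the ENM's predicted apparent-stiffness profile
match the experimental one.  Because k_app folds in the whole network, the
table is refined iteratively:

1. build one network per protein from the representative structure under
   the current table, with springs assigned by the ensemble-mean distances
   (the same discretised equilibrium distance that bins the profiles —
   assigning by the representative's noisy distances instead leaves a
   pair-level inconsistency that shows up as a persistent drift of the
   table whenever k(d) has sharp features);
2. fit the temperature factor per protein, propagate pair variances, and
   aggregate the predicted profile with the same weights and correction as
   the experimental one;
3. update multiplicatively, k ← k · k_exp/k_pred — the unique form whose
   fixed point is k_pred = k_exp and which cannot drive k negative;
4. rescale so the mean k over amino-acid pair types at the 6 Å bin is 1;
5. cull entries below θ = 1e-3 (set to 0, permanently: no direct
   interaction), and mirror entries of data-empty bins from the nearest
   supported bin so the bonded-spring rule keeps tracking the refined
   short-range constants.

Modes: `distance_only` (dENM, one curve over 3–15 Å), `sequence_only`
(sENM, one constant per pair type below a 10 or 13 Å cutoff, initialised
from the pooled experimental stiffness below the cutoff) and
`sequence_distance` (sdENM, per-type curves initialised by replicating a
dENM result).  Default selection iterations are 5 (dENM), 1 (sENM) and 3
(sdENM).  Proteins whose network degenerates under the current table are
skipped with a logged warning; more than 10 % skipped aborts the run.
Bootstrap confidence intervals resample proteins with replacement
(default 100 replicates, 90 % level, empirical quantiles per entry),
restarting each replicate from the standard initialisation.

Convergence behaviour, measured on synthetic ground truths: the iteration
is a contraction with rate roughly 0.75–0.85 per step.  Smooth ground
truths are at their fixed point immediately (one iteration moves populated
entries by ≲2 % at realistic data volumes).  An adversarial ten-fold step
in k(d) right at the 6 Å reference distance starts far from its target
(the apparent-stiffness initialisation compresses the true contrast
several-fold) and therefore still shows ~35 % worst-bin error after 5
iterations, ~26 % after 9, decreasing steadily.  The per-type *contrasts*
converge much faster than the distance *shape*: sequence-specific ground
truths are recovered with log-k correlation r ≈ 0.95 over well-populated
entries after the default schedule.  Users deriving tables from data with
suspected sharp distance structure should inspect the per-iteration change
recorded in the history and extend the schedule.

## Performance measures

r_B is the Pearson correlation between predicted and experimental MSRF
(undefined, reported missing, when either side is constant).  The pairwise
error

    ε_σ = (1/N_pairs) Σ min(1, |σ_pred − σ_exp| / σ_unc)

runs over non-bonded pairs; σ are standard deviations of inter-residue
distances, σ_pred is computed after the per-protein temperature fit, and
the normalisation by the decorrelated expectation σ_unc makes pairs
commensurate instead of letting floppy regions dominate.  Per-pair signed
deviations are clamped to ±1 (the clamp is switchable; deviations are of
σ, not σ²).  ε_σ is reported whole and split by equilibrium separation
into 0–15, 15–30 and >30 Å ranges; aggregates over proteins are unweighted
means.

## Synthetic data and oracles

`simulate.generate_dataset` builds protein-like fixtures with known ground
truth: self-avoiding compact Cα chains (3.8 Å spacing, ≥4.0 Å non-bonded
separation, ~110 Å³ per residue confinement — `radius_scale` loosens it),
random sequences, and ensembles drawn from the network's exact harmonic
Boltzmann distribution via its eigenmodes.  Classic-model fixtures default
to γ = 3 kBT/Å², i.e. RMS residue fluctuations ≈ 0.45 Å (B ≈ 12 Å²) — a
well-ordered protein, and small enough that sampled bonds never cross the
chain-break threshold.  Optional 5-residue tails grown without confinement
and sprung at 1/20 of the reference value produce MSRF > 2× the mean, so
the trimming rule is exercised end to end.  With
`include_equilibrium_model` the exact equilibrium conformation is inserted
as a model, so representative selection recovers the true input structure;
self-consistency oracles use this to test the scoring machinery rather
than input-structure sampling noise (rebuilding a cutoff network from one
noisy model flips contacts near the cutoff and caps r_B well below 1).

The independent dynamics oracle is overdamped Euler–Maruyama integration
of the *nonlinear* network potential with unit friction,
x ← x − dt∇V + √(2 kBT dt) ξ, default dt = 0.1/λ_max and snapshot stride of
ten relaxation times of the slowest mode (tests use denser strides; samples
1–2 relaxation times apart are already nearly independent).  Its
equilibrium statistics agree with the harmonic sampler on compact fixtures
(MSRF correlation > 0.95), which validates the linearised covariance the
analysis pipeline relies on.

What the synthetic benchmarks do **not** establish: real NMR ensembles are
not Boltzmann samples of a harmonic network — model counts are small,
restraint density varies along the chain, and conformational heterogeneity
is non-Gaussian.  Passing fixtures therefore demonstrates correctness of
the estimators and the derivation machinery, not the physical accuracy of
any derived potential on experimental data.

## Numerical and degenerate-input choices

* Zero-mode tolerance 1e-8 × λ_max; symmetric matrices are symmetrised
  after reconstruction to purge roundoff asymmetry.
* Representative ties break to the lowest model index; bin edges are
  half-open [left, left + Δ).
* Tail trimming and validation never mutate their input ensemble.
* Distance variances of coincident points, zero experimental variances in
  a confrontation, empty profiles, a culled reference bin and an sdENM
  initialisation without a dENM table are all hard errors with specific
  messages.
* The Langevin integrator aborts when any coordinate passes 10³ Å and
  rejects dt beyond the 2/λ_max stability bound.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the fixture spec / derivation config; rerunning any pipeline command with
  the same configuration and seed reproduces outputs byte for byte.
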