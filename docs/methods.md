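# Methods

## Free-energy estimation

All estimators operate on reduced potentials u_k(x) = U_k(x)/kT and
return dimensionless free energies anchored at f₀ = 0; the reporting
layer converts to kJ/mol with kT = R·T (default T = 300 K, configurable
everywhere a unit conversion happens).

**MBAR.** The free energies satisfy the self-consistency equations

    f_i = −ln Σ_n exp(−u_i(x_n)) / Σ_k N_k exp(f_k − u_k(x_n)).

`mbar_solve` minimises the equivalent convex objective
Σ_n ln Σ_k N_k exp(f_k − u_kn) − Σ_k N_k f_k with L-BFGS (gradient
supplied analytically), then polishes with self-consistent iteration
until the largest per-sweep free-energy change is below the tolerance
(default 1e-8).  Initialisation is deterministic at f = 0.  States with
N_k = 0 are allowed as evaluation-only states and are filled in after
convergence.  Every exponential average in the package goes through
log-sum-exp; this is a correctness requirement (reduced potentials of
poorly overlapping states overflow a naive mean of exponentials), not an
optimisation.

**Uncertainty.** The asymptotic covariance of the f_k uses the
singular-value-decomposition form: with W the N×K weight matrix
(W_nk = exp(f_k − u_kn)/Σ_l N_l exp(f_l − u_ln)) and N = diag(N_k),

    Θ = V S (I − S Vᵀ N V S)⁺ S Vᵀ,   W = U S Vᵀ,

re-anchored so Cov involves differences from state 0.  σ(Δf_ij) is then
the usual quadratic form; it is zero for i = j and for perfectly
correlated (identical) states.  A sampled state whose weight column sums
to ~0 (singular weight structure) raises an error naming the state.
Calibration: over repeated seeded draws of a harmonic pair, the
empirical scatter of Δf estimates agrees with the mean reported σ to
well within 30% (tested).

**EXP and BAR** are implemented as baselines/cross-checks only:
EXP as Δf = −ln⟨e^(−w)⟩ via log-sum-exp, BAR by bracketed root finding
on the monotone Fermi-function balance with M = ln(N_F/N_R).  At K = 2,
MBAR and BAR agree to solver tolerance (tested to 1e-7); for Gaussian
work, EXP converges to μ − σ²/2.

**Overlap diagnostics.**  The overlap matrix O_ij = Σ_n W_ni N_j W_nj is
row-stochastic (rows sum to 1 exactly, up to round-off) and reduces to
1/K for identical states.  The per-adjacent-pair overlap/bias gate is

    Π = min over the two directions of [ √(2 ln N) − √(2 s) ],

where s is the relative (Kullback–Leibler) entropy between the two
states estimated from the sampling direction's own samples,
s = (f_i − f_j) + ⟨u_j − u_i⟩_i ≥ 0, and N the sample count of that
direction.  Rationale: the dominant integrand region of an exponential
average sits ~s below the sampled distribution's typical set, so it is
visited with probability ~e^(−s); a sample of size N explores ~ln N nats,
and for Gaussian work distributions √(2s) equals the work sd, making Π a
signal-to-sampling margin.  Π ≥ 0.5 is adequate (the boundary passes);
a failing pair is reported as a recommendation to insert a λ midpoint.
The threshold and the qualitative behaviour (near-identical states pass
at N = 10⁴, distributions 20σ apart fail) are the contract; the exact
functional form is this package's transcription of the large-sample
reliability heuristic.

**Not implemented:** decorrelation/subsampling of time series.  Samples
are taken as given and the asymptotic σ assumes independence; correlated
input will make σ overconfident.  This is deliberate — the ensemble SE
over independent replicas, not the single-run σ, is the recommended
uncertainty.

## Ensemble statistics

* Ensemble SE uses the sample sd with the n−1 denominator divided by √n
  (this convention reproduces every self-consistent printed SE in the
  packaged fixtures).
* The precision ratio divides the ensemble SE by the *arithmetic mean*
  of the replicate σ_MBAR values; min- or single-replicate denominators
  are possible alternatives but the mean is the package convention.
* Cycle closure enumerates the full Cartesian product of replicate
  choices (deterministic, lexicographic in replicate index).  The quoted
  `se` is the quadrature sum of per-transformation ensemble SEs; the
  spread over combinations is reported separately (`sd_combinations`).
  A transformation traversed against its stored direction contributes
  with sign −1; reversal is explicit (negate ΔΔG, keep σ).
* `compare_conditions` pools all 2n values for the null (grand mean,
  pooled sample sd of the combined values), then asks how often two
  freshly drawn Gaussian groups of the observed sizes differ in mean by
  at least the observed amount.  Monte-Carlo default is 10⁶ repetitions
  (seeded, seed echoed); the analytic two-sided normal tail with
  sd·√(1/n_A + 1/n_B) agrees with the Monte-Carlo estimate within
  binomial noise (tested at 3σ).  The observed threshold uses unrounded
  means.  Type-I calibration: on offset-free synthetic studies, p < 0.1
  fires in ≈10% of cases (tested at ±4 binomial σ over 500 studies).

## Quality metrics

* Errors are calculated − experimental, in kJ/mol; MAD and Max are mean
  and max absolute error.
* R² is computed bidirectionally: the point set is augmented with the
  sign-mirrored point of every transformation, which forces exact zero
  means and reduces R² to (Σxy)²/(Σx²·Σy²).  This removes the arbitrary
  choice of perturbation direction.
* Kendall τ_r is an explicit pair census over the studied
  transformations only.  Two denominators exist and are never silently
  mixed: `tie_policy="count"` divides by all pairs (ties contribute 0) —
  the default for τ_r; `tie_policy="exclude"` divides by untied pairs
  only — the default for τ_r90, where a tied experimental difference is
  by definition not significant.  τ_r90 additionally drops
  transformations with |calc| < 1.645·SE (two-sided normal 90% level;
  the multiplier is a parameter, and a t quantile was deliberately not
  used because the normal multiplier reproduces the packaged studies'
  inclusion/exclusion pattern) and, when an experimental σ is supplied,
  applies the same test to experiment.  Fewer than two survivors →
  τ_r90 is undefined (None), not an error.
* Direction invariance: MAD, Max and R² are exactly invariant under
  reversing any individual transformation (both values flip sign).  The
  pair-census τ is invariant only under a *global* reversal; individual
  reversals can change the census — an intrinsic direction-dependence of
  rank concordance on relative quantities, inherited by any convention
  that reproduces the published pair counts.
* Experimental lower bounds are used at face value and flagged in the
  report (`uses_bound_values`).
* Bootstrap: each of the (default 1000) sets perturbs every calculated
  value by Gaussian noise with its SE, and every experimental value by
  its σ where provided; the sd over sets is the quoted uncertainty,
  while the central value is always the unperturbed point estimate.
  With the ensemble SEs of the packaged studies this yields MAD
  uncertainties of ~0.06–0.08 kJ/mol; published uncertainties of that
  style are sensitive to the (often unstated) choice of perturbation
  scale, so only structural properties (zero-SE → zero sd, linear
  scaling in the SEs) are asserted, not specific published ± values.

## Synthetic data (what a green test establishes)

* `gen_harmonic_alchemy` builds 1-D harmonic λ states
  u_k(x) = ½k_k(x−c_k)², whose exact free energies
  Δf = ½ ln(k_i/k_0) are independent of the centers.  It exercises the
  estimators' numerics (overlap, bias, covariance) exactly, but not
  force-field error, time correlation or conformational trapping — a
  green estimator test certifies the statistics, not an MD result.
* `gen_replicate_study` draws replicate ΔΔG values i.i.d. Gaussian
  around a stated truth (default scatter 0.39 kJ/mol, 5 replicates per
  condition, matching the canonical situation analysed here), with an
  optional systematic offset on one condition.  Real replicate scatter
  need not be Gaussian or i.i.d.; the generator states the null model
  the comparison test assumes.
* `gen_water_box` places rigid TIP3P-geometry waters (O–H 0.9572 Å,
  H–O–H 104.52°) on a jittered cubic lattice with uniform random
  orientations.  Defaults: jitter 0.2 Å, which with the minimum allowed
  lattice spacing (2.4 Å O–O) keeps all oxygen pairs ≥ 2.4 Å apart.
  Boxes are geometric stand-ins: no interaction model, no equilibration,
  no hydrogen-bond structure.  They exercise the overlay/cull machinery,
  not solvent physics.
* All generators use numpy's PCG64 (`default_rng`) and record their
  seed; identical seeds give bit-identical output.

## Solvation replicas

The target box is the solute bounding box plus a margin (default 12 Å)
per side, cubified, with the solute centred.  The snapshot is rigidly
rotated (uniform quaternion) and translated (uniform within one box
period) by a seeded generator — `seed=None` keeps the identity — then
tiled over its periodic images; a water belongs to the system if its
oxygen lands inside the target box, and molecules are always kept or
deleted whole.  Culling removes a water if any of its atoms is within
the clash cutoff (default 2.4 Å, an approximate heavy-atom van der Waals
contact; neither the margin nor the cutoff has a canonical published
value, so both are explicit parameters) of any solute atom, using a k-d
tree; distances are plain Euclidean in the final box frame (no
minimum-image across the final box boundary, matching the usual
pre-equilibration overlay practice).  Counterion placement is out of
scope; the manifest records the required net charge as metadata.

Degenerate inputs: an empty solute with the identity transform and a
margin of half the snapshot edge reproduces the snapshot exactly
(count-conserving, no seam deletions); a cutoff ≥ margin triggers a
pathological-culling warning rather than an error.

## Numerical choices

* MBAR tolerance 1e-8 on the max free-energy residual; ConvergenceError
  carries the final residual.
* BAR: Brent root finding to 1e-10 inside an automatically expanded
  bracket seeded by the two EXP estimates.
* Π requires ≥ 10 samples per state (the measure is meaningless at
  trivial N) and clamps estimated relative entropies at 0 before the
  square root.
* Printed-precision fixture tests allow one unit in the last printed
  digit, absorbing the source tables' own rounding.
* `run_study` derives per-stage seeds from the top-level seed via a
  fixed affine map (recorded in the report), keeping them below 2³¹.

## Known limitations

* No autocorrelation handling anywhere; all SEs assume independent
  samples/replicas.
* No hierarchical pooling across transformations; each is analysed
  independently.
* τ is restricted to explicitly studied transformations; chained ligand
  pairs are deliberately not scored.
* The water boxes and harmonic ladders are statistical stand-ins, not
  physical systems; agreement there does not validate any force field
  or sampling protocol.
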