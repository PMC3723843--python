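# Methods

## The screening problem

A pairwise interaction screen over n targets (drugs or genes) has
n(n−1)/2 candidate experiments, each measuring an interaction score
ξ_ij for a pair (i, j).  With viability-ratio phenotypes the score is
the Bliss deviation ξ_ij = w_ij − w_i·w_j; negative scores mark
synergy.  Exhaustive screening scales quadratically with library size,
so `synscreen` instead aims to find a high fraction of the synergistic
pairs while testing a small fraction of all pairs, by steering the
order in which pairs are measured.

## Screening efficiency

A screen is summarised by F(f), the mean fraction of all synergies
discovered after testing a fraction f of all pairs.  Uniform random
("brute force") testing gives E[F(f)] = f.  A strategy whose fractional
discovery rate dF/df is a constant factor η above the brute-force rate
satisfies the differential equation dF/df = η(1−F)/(1−f) with F(0)=0,
whose solution is

    F(f) = 1 − (1 − f)^η.

η = 1 is brute force; the oracle (testing only true synergies) attains
η = 1/p where p is the synergy prevalence.  `estimate_eta` fits η by
least squares on the linearisation log(1−F) = η·log(1−f) through the
origin, over all checkpoints of the observed curve, excluding
saturated points (F = 1) where the logarithm is undefined.  A
single-checkpoint estimator `eta_from_point` is also exposed for
statements of the form "X% of synergies from 20% of experiments".

Two caveats documented deliberately: (i) the oracle curve
F = min(f/p, 1) is outside the 1−(1−f)^η family, so its fitted η
exceeds 1/p as the fit approaches saturation — the oracle bound is the
analytic 1/p, not a fit; (ii) for real screens without ground truth,
F can only be computed against synergies-found-so-far, and traces carry
a `ground_truth_known` flag so such curves are never presented as
absolute discovery rates.

## Propensity model

Hubness is modelled per target: the probability π_i that a random pair
involving target i is synergistic gets a conjugate Beta(a, b) prior,
and with s_i synergies in n_i tested pairs the posterior mean is
π_i = (s_i + a)/(n_i + a + b).  Untested pairs are drawn without
replacement with probability ∝ π_i·π_j (implemented by Gumbel-key
sampling, distributionally identical to sequential renormalised
draws).  The default prior is a = 0.5, b = n: a prior mean of roughly
1/(2n) encodes the belief that few targets are hubs.  The flat
Beta(1, 1) alternative — a prior mean of one half — adapts slowly and
measurably reduces efficiency, and is kept only as a comparator.  The
shapes can also be estimated from per-target counts by empirical Bayes
(`fit_beta_binomial`): marginal beta-binomial likelihood maximised in
(log a, log b) with Nelder–Mead from three starting points (moment
estimate plus fixed alternatives) to avoid boundary traps; the
all-zero-count boundary case is flagged as not converged.

## Matrix completion by cyclic projections

Unobserved scores are predicted by finding a symmetric matrix in the
intersection of three convex sets: C1, matrices agreeing with the
measurements D on the observed set Ω; C2, matrices of bounded nuclear
norm (the convex surrogate for the modular, block-low-rank structure of
interaction networks); and C3, matrices consistent with a functional
similarity kernel Q.  Q is symmetric, non-negative, zero-diagonal and
bistochastic, so QM replaces each row of M by the weighted average of
its functionally similar rows; consistency means (I−Q)M is small.  The
zero diagonal excludes the trivial Q = I solution.

Rather than exact set projections, each set is handled through the
proximal map of a penalised objective — for a given set radius there is
a penalty giving the same solution, and the penalised forms are closed
form:

* C1: X = (M + λ1·D)/(1 + λ1) on Ω, X = M elsewhere.  λ1 defaults to
  10; values near zero would treat the data as non-informative and are
  warned against.
* C2: soft-thresholding of the singular values, σ → max(σ − λ2, 0).
  For symmetric input this is computed through the eigendecomposition
  (singular values are |eigenvalues|), which keeps the output exactly
  symmetric and deterministic; above n = 500 only the leading
  eigenpairs exceeding the threshold are computed, growing the
  truncation rank adaptively.
* C3: X = (I + λ3·(I−Q)ᵀ(I−Q))⁻¹ M, followed by symmetrisation
  (X + Xᵀ)/2.  The system matrix is identity-plus-PSD, so the Cholesky
  factor always exists and is cached across iterations; each
  application is then two triangular solves.  The left-application
  residual (I−Q)X is the kernel-interpolation reading; a symmetrised
  residual X − (QX + XQ)/2 is available behind a config switch.  The
  unconstrained proximal minimiser is not exactly symmetric for
  symmetric M (the solve and M need not commute), so the operation
  symmetrises; tests verify the core solve against a numeric minimiser
  and that the symmetrised output still lowers the penalised
  objective.

The solver starts from the zero matrix and cycles C1 → C2 → C3 until
the relative Frobenius change per cycle drops below tol = 1e-4
(max_iter 500).  All three maps are proximal operators of convex
functions, hence (firmly) non-expansive, which is what makes the cyclic
scheme stable; the property suite checks non-expansiveness directly.
If the penalised sets fail to intersect the iteration settles into a
limit cycle; this is detected when the iterate revisits the value from
two cycles earlier (max deviation < 1e-6) while the relative-change
series has stopped decreasing for three consecutive cycles, and the
average of the last cycle's three step outputs is returned as a point
close to all sets, flagged `limit_cycle`.  With λ3 = 0 and λ1 → ∞ the
iteration is exactly SoftImpute, which the tests verify elementwise.

λ2 and λ3 are chosen by 5-fold cross-validation: 20% of observed pairs
held out per fold, completion run on the remainder, scored by the
Pearson correlation between held-out measurements and predictions,
averaged over folds; argmax with ties broken toward larger λ2 (then
λ3).  The λ2 grid is specified as fractions of the largest singular
value of the zero-filled data (default 8 log-spaced points in
[0.01, 0.5]); the λ3 grid is 7 log-spaced points in [0.01, 100].  A
fold whose held-out truth is constant is skipped with a warning; a
constant *prediction* (full shrinkage) scores r = 0, not an error —
otherwise the heavy-shrinkage end of the grid could never win.  On
structureless data the CV surface is flat near zero and the argmax is
driven by chance correlations, so only averaged-over-seeds statements
about selected penalties are meaningful; the tests are phrased
accordingly.

## Adaptive protocols

* Algorithm 1 (propensity only): repeat {re-estimate π from counts so
  far; draw a batch of n_a untested pairs ∝ π_i·π_j; measure; update
  counts}.
* Algorithm 2 (full protocol): after each propensity batch, complete
  the observed matrix and greedily test the n_b untested pairs with the
  most negative predicted scores ("most extreme" read as most
  synergistic; absolute-value ranking is a config switch).  The batch
  hit rate (synergies per experiment) of the latest prediction batch is
  compared with that of the latest propensity batch; prediction mode
  continues only while strictly ahead — ties revert to propensity, and
  the first batch of a screen is always propensity (completion needs
  observations).  Completion is re-fit once per prediction batch;
  cross-validated penalties can be computed once at the first
  prediction batch and cached (`cv_lambdas`), the default being fixed
  penalties (λ2 at 0.1 of the top singular value of the current
  zero-filled data, λ3 as configured) for tractability inside the
  loop.

Defaults: n_a = n_b = 1% of all pairs, stop fraction f_max = 0.5.  All
randomness flows from one integer seed; identical config and seed give
byte-identical traces.

## Synthetic systems

The generator emulates the three statistical features of real
interaction compendia that the method exploits: (i) modular signal —
targets are split into k modules and each module pair receives a mean
score, most ~N(0, σ_b²) and a configured minority (default 20% of
module pairs) shifted negative by ~3σ_b plus an exponential excess,
giving a rank ≤ k block signal with a long, non-normal negative tail
(excess kurtosis and negative skew are asserted in tests);
(ii) hubs — a default 10% of targets have the negative part of their
rows/columns amplified (default ×3), so they accumulate
disproportionately many synergies, the premise of the propensity
model; (iii) iid Gaussian noise (default SD 0.5 on a block-mean SD of
1).  The synergy threshold is calibrated by direct quantile inversion —
the midpoint between the order statistics bracketing the requested
prevalence — which is the closed form of a bisection on the threshold
and hits the target prevalence to within one pair; a fixed threshold
(e.g. a 3-SD rule via `sd_threshold`) can be supplied instead.

The matching similarity kernel `informative_q` mixes the true
module-label kernel with a random bistochastic kernel at a chosen
fidelity, emulating real similarity sources (PPI, GO, mechanism of
action) that explain only part of the interaction structure; the
explained fraction max(0, 1 − ‖M − QM‖²_F/‖M‖²_F) increases
monotonically in fidelity.

What the generator does not emulate: dose–response surfaces and raw
plate effects, empirical marginal distributions of any specific
published dataset, correlated or heteroscedastic noise, and
interactions that defy the modular pattern.  Passing tests therefore
demonstrate correctness of the machinery and the expected qualitative
ordering of strategies under the method's own assumptions, not
performance guarantees on real screens — on real data, interactions
that deviate from modularity and hubness are harder for this method to
find, by construction.

## Problem sizes in the tests and acceptance script

Screening benchmarks use n = 200 targets (19 900 pairs) at 5%
prevalence with screens run to f_max = 0.3, averaged over 30 seeds in
the tests and 10 seeds in the acceptance script; completion benchmarks
use rank-2 modular 100×100 systems with 80% of pairs unobserved and
noise at 10% of the signal SD.  These sizes sit at the small end of the
regime the method targets (it favours larger systems, where there is
more room to improve on brute force) and were chosen so the whole
study re-runs comfortably on a laptop-class machine.

## Numerical choices

* Convergence: relative Frobenius change < 1e-4 per cycle (1e-7 for
  the initialization-robustness check, where the question is whether
  different starts reach the same fixed point to < 1e-4 elementwise).
* Bistochastic scaling: symmetric Sinkhorn–Knopp, d ← d/√(row sums),
  tolerance 1e-8 on row sums, cap 1000 sweeps; preserves symmetry and
  the zero diagonal exactly; a zero row (target with no similarity
  support, e.g. a singleton group) is an error.
* Matrix TSV round-trips use "NA" for unobserved entries; asymmetry
  beyond 1e-9 on read is an error, below it values are averaged.
* Ties in prediction ranking are broken by stable sort order;
  sampling ties are resolved by the seeded RNG.
* `sd_threshold` uses the sample SD (ddof = 1); a zero-spread score
  collection degenerates to the constant and warns.

## Known limitations

* η estimates from a single screen realisation are noisy at small n;
  comparisons between strategies should always be made as means over
  seeds (the paired tests do).
* The hit-rate switching rule compares single batches, so with small
  batches (few pairs) the mode decision is itself noisy.
* CV inside the screening loop is expensive; the default fixed-penalty
  heuristic trades a little accuracy for an order-of-magnitude less
  compute.
* The similarity projection assumes Q is informative about the *score*
  structure; a misleading Q (fidelity near 0 with λ3 large) can hurt
  completion accuracy.  λ3 = 0 recovers the prior-free method.
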