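# synscreen

Adaptive pair screening for synergistic drug or gene combinations.

Pairwise screens — drug-combination panels, double-knockout genetic
arrays, combinatorial RNAi — grow quadratically with library size:
n targets mean n(n−1)/2 experiments.  `synscreen` implements a
computational–experimental protocol that finds most of the synergistic
pairs while testing only a small fraction of all pairs, by letting the
screen's own early findings steer which pairs are measured next.

## The method

An interaction score for a pair (i, j) is the Bliss deviation

    ξ_ij = w_ij − w_i · w_j,

where w_i, w_j, w_ij are relative phenotypes (e.g. viability ratios)
after single and combined perturbation; pairs with ξ below a threshold
(typically some standard deviations under the score mean) are called
synergistic.  The protocol interleaves two search modes:

1. **Propensity-biased sampling.**  Each target's propensity to
   synergise gets a Beta(a, b) prior; with s_i synergies in n_i tested
   pairs the posterior mean is π_i = (s_i + a)/(n_i + a + b), and
   untested pairs are sampled with probability ∝ π_i·π_j — the screen
   homes in on interaction hubs as it runs.
2. **Prediction-driven selection.**  The partially observed score
   matrix is completed by cyclic projections onto three convex sets —
   agreement with the data, bounded nuclear norm (modular, low-rank
   structure), and consistency with a bistochastic functional-similarity
   kernel Q — and the most negative predicted untested pairs are tested
   greedily.  With the similarity set dropped and a hard data
   constraint, the iteration reduces exactly to SoftImpute.

A hit-rate rule switches between the modes: prediction batches continue
while they yield strictly more synergies per experiment than the last
propensity batch.  Performance is measured by the screening efficiency
η in F(f) = 1 − (1−f)^η, where F is the fraction of synergies found
after testing a fraction f of pairs: η = 1 is uniform random screening,
and 1/prevalence is the oracle ceiling.

A synthetic-system generator (modular block signal, interaction hubs,
Gaussian noise, matched similarity kernels) makes the whole framework
testable end to end without external data.

## Worked example

```python
import numpy as np
import synscreen as s

# a 200-target system: 5 functional modules, 10% of targets are hubs,
# threshold calibrated to 5% synergy prevalence
system = s.simulate_system(n=200, k=5, target_prevalence=0.05, seed=7)
Q = s.informative_q(system, fidelity=1.0, seed=7)

for mode, q in [("brute", None), ("algorithm1", None), ("algorithm2", Q)]:
    cfg = s.ScreenConfig(
        mode=mode, seed=7, f_max=0.3,
        completion=s.CompletionConfig(lambda3=1.0),
    )
    trace, est = s.run_screen(cfg, system, q)
    F = trace.n_synergies_found / trace.total_synergies
    print(f"{mode:11s} eta={est.eta:5.2f}  "
          f"found {F:.0%} of synergies testing {trace.fraction_tested:.0%}")
```

prints

```
brute       eta= 0.87  found 28% of synergies testing 30%
algorithm1  eta= 3.25  found 66% of synergies testing 30%
algorithm2  eta= 4.38  found 68% of synergies testing 30%
```

Brute force discovers synergies at about the rate it tests pairs
(η ≈ 1 in expectation; a single replicate is noisy).  Propensity-only
screening (algorithm1) finds them ~3× faster, and the full protocol
with matrix-completion-guided batches (algorithm2) faster still — here
68% of all synergistic pairs from 30% of the experiments, against the
oracle ceiling of 1/0.05 = 20.  Averaged over seeds the gap widens
(see the acceptance study below).

The same pipeline is available from a shell:

```
synscreen simulate --n 200 --modules 5 --prevalence 0.05 --seed 7 --out-prefix sys7
synscreen screen --scores sys7.scores.tsv --mode algorithm2 --q sys7.q.tsv \
                 --fmax 0.3 --seed 7 --out trace.csv
synscreen evaluate --trace trace.csv --out eta.json
```

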