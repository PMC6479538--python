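# Methods

## Model and procedure

`alarmforest` studies probability and class assignment inside a bagged
forest for imbalanced binary alarm classification. The pipeline is:

1. **Forest.** m trees (default 500, the size used throughout the
   package's illustrations) are grown on bootstrap samples of size n drawn
   with replacement, unpruned, with minimum leaf size 1 and mtry features
   tried per split (default floor(sqrt(p)); a printed source convention of
   floor(p) would disable feature subsampling entirely, so the standard
   classification default is used and both are configurable). Tree
   induction is delegated to scikit-learn's `RandomForestClassifier`;
   In-Bag flags are recovered per tree by replaying its bootstrap draw
   from its recorded random state, then binarized (count ≥ 1 → 1) —
   multiplicity is never used downstream.
2. **Trace.** The n × m per-tree probability matrix plus the n × m In-Bag
   flag matrix. All aggregation schemes are deterministic functions of the
   trace, so all ten methods share one fitted forest per fold.
3. **First-level probability.** Per observation, over the trees of a scope
   (INB / OOB / all): the mean probability (`Avg Prob`) or the YES-vote
   fraction with tree votes cast at per-tree Youden cutoffs derived on the
   tree's In-Bag sample (`Voting Prob INB`), on the whole training sample
   (`Voting Prob Train`), or at the fixed 0.5 (`Voting Prob 0.5`). Tree
   cutoffs are per-tree because In-Bag membership is tree-specific; a
   single global threshold can be passed instead.
4. **Second-level class.** The final cutoff is fixed 0.5 or
   Youden-optimized on the INB-scope or TRAIN-scope probability vector of
   the training fold. The ten (scheme, cutoff-source) combinations are the
   method matrix; validation observations always use all trees with
   cutoffs frozen on the training fold.
5. **Evaluation.** AUC, challenge score, TPR, TNR on the train / INB /
   OOB / validation samples under adaptive stratified k-fold CV; mean ±
   SE (sd/√k) over folds.
6. **Rank aggregation.** Per-dataset rankings by validation AUC (4
   probability schemes) or score (10 methods), ties broken by a seeded
   random permutation; global ordering by exhaustive minimization of the
   total weighted Spearman footrule distance; repetition of the random
   tie-breaking yields item × position frequency tables.

## Conventions and numerical choices

- **Vote/classification rule.** YES iff the probability *strictly*
  exceeds the cutoff, at both levels. A voting probability of exactly 0.5
  at final cutoff 0.5 is therefore NO, deterministically. A `random` tie
  mode (fair coin from the run's generator) is available for the classical
  random tie assignment of majority voting, but the deterministic rule is
  the default so runs are exactly reproducible.
- **Threshold candidates.** Midpoints between consecutive distinct scores,
  plus one sentinel below the minimum (the all-YES rule) and the maximum
  score itself (the all-NO rule under strict >). This realizes a threshold
  sweep exactly, with no arbitrary grid; a fixed grid can be passed for
  strict replication of grid-based sweeps. Because scores may be monotone
  transforms of probabilities in property checks, the low sentinel may lie
  below 0; a reported threshold below the minimum score encodes "classify
  everything YES".
- **Youden ties.** Among thresholds maximizing J = TPR + (1 − FPR), the
  smallest is returned. This favors sensitivity, consistent with the
  fivefold FN penalty of the challenge score, and is deterministic.
- **AUC.** Trapezoidal area under the midpoint-threshold ROC, which equals
  the Mann–Whitney rank statistic with ties counted one half; tests verify
  that equivalence against brute-force pair counting.
- **Degenerate inputs.** Single-class datasets are rejected at
  construction. A tree whose cutoff-derivation subsample is single-class
  falls back to 0.5 with a logged warning. An observation whose scope
  contains zero trees (never In-Bag, or never OOB) gets an *undefined*
  probability: it is flagged, logged, and excluded from cutoff derivation
  and metrics — never silently assigned a class.
- **Cross-validation.** k = 10, or the minority class size when that is
  ≤ 10 (so every fold holds at least one observation of each class; 9 and
  6 for the extreme-tachycardia and ventricular-fibrillation imbalances).
  Stratification: within each class, shuffle (seeded) and deal round-robin,
  so per-fold class counts are the floor/ceiling of the proportional
  share. Folds are shared across methods, which are post-hoc readings of
  the same per-fold trace. Fold-level failures become NaN rows, not run
  aborts.
- **Rank aggregation.** The footrule objective decomposes over (item,
  position) pairs, so a linear-assignment solve gives the optimal value;
  a depth-first enumeration with a cheapest-open-position lower bound then
  recovers *all* co-optimal permutations (the exhaustive search the
  method calls for, pruned). σ\* is the lexicographically smallest
  co-optimum, for determinism. Aggregation refuses k > 10. A
  squared-displacement (Spearman ρ-style) distance is available; footrule
  is the default.
- **Seeding.** Every entry point takes one seed; internal streams (fold
  assignment, per-fold forests, tie-breaking) are spawned from it via
  `numpy.random.SeedSequence`, so components are independently
  reproducible.

## Synthetic data

The generator emulates the five-arrhythmia alarm suite: five datasets with
the real class imbalances (252/89, 100/22, 9/131, 52/6, 43/46; 750 total)
but class-conditional Gaussian features — informative features are
N(0, 1) for NO and N(delta, 1) for YES, the rest pure noise. Defaults:
p = 10 features with 3 informative (alarm classifiers in this setting use
small heart-rate-derived feature sets), delta = 1.5, giving a
single-feature Bayes AUC Φ(delta/√2) ≈ 0.86 — inside the validation-AUC
band typical of real per-arrhythmia alarm classifiers. The closed-form
Bayes AUC makes the generator an oracle: at delta = 0 every method must
sit at chance, and at p = 1 the empirical feature AUC must converge to
Φ(delta/√2).

What the generator does *not* emulate: waveform artifacts, label noise,
correlated or discrete features, and the impure-leaf regime they induce.
On clean continuous features fully grown trees have pure leaves, so
per-tree probabilities are 0/1 and the four probability schemes largely
coincide; passing tests on synthetic data therefore validate the
machinery and its contracts, not the real-data performance differences
between schemes (the hand-built fractional trace covers the distinctions
explicitly).

## Problem sizes used in the shipped checks

The test suite and the reference script run at deliberately modest sizes
chosen to estimate the quantities they check well: forests of 12–100
trees on datasets of 22–1000 observations for behavioural checks, one
500-tree fit for the trace-shape contract, a 20-replicate bootstrap
simulation at n = 100,000 for the 63.2%/36.8% In-Bag/Out-of-Bag law, 200
random instances (n ≤ 30) for the optimizer-vs-oracle equivalences, and
25–200 tie-breaking repetitions for rank-distribution structure.

## Known limitations

- In-Bag flag recovery relies on a scikit-learn private helper
  (`_generate_sample_indices`); a backend change there would surface
  immediately in the trace-contract tests.
- Exhaustive rank aggregation is limited to 10 items by design; the
  stochastic alternatives used for larger problems are out of scope.
- AUC confidence intervals, probability calibration, and weighted-voting
  ensemble variants are out of scope.
- The challenge score is undefined on empty samples and is reported as
  NaN-free only because undefined-probability observations are excluded
  before scoring; heavily depleted scopes therefore shrink the scored n,
  which is logged.
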