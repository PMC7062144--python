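# Methods

This note documents the models, algorithms and numerical choices behind
`btrlearn`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate.

## BTR model semantics

A BTR model over a features × samples abundance matrix selects `k` features
and assigns each a discrete coefficient: `{1}` for Bin (cumulative
abundance of one group), `{-1, 1}` for Ter (difference of two groups'
cumulative abundances), or a numerator/denominator side tag for Ratio
(quotient of two groups' cumulative abundances, intercept fixed at zero).
TerLog is Ter fitted on log-transformed abundances, i.e. a multiplicative
balance. The decision is `positive_class` iff score > threshold (direction
`score_greater`) or score < threshold (`score_less`); the comparison is
strict and ties go to the non-positive class. Fixing strictness plus a
learned direction flag subsumes both the `<` and `≥` forms a reader might
write for the same rule.

**Ratio sentinels.** On sparse data a ratio denominator can be zero. We
define x/0 → +∞ for x > 0 and 0/0 → 0, which keeps predictions defined on
presence-heavy profiles and interacts correctly with the threshold sweep
(+∞ scores sort above every finite cut).

**Canonical form.** A Ter model and its global sign flip — or a Ratio model
with numerator and denominator exchanged — encode the same decision rule
with the direction reversed. Populations store the canonical
representative (features sorted by index, first coefficient +1), halving
the effective search space; the exhaustive enumerator counts
`C(p,k) · 2^(k-1)` canonical sign patterns per size (`C(p,k)` for Bin).

**Scale invariance and floating point.** Ratio scores are mathematically
invariant to per-sample rescaling. In IEEE arithmetic `c·(a+b)` and
`c·a + c·b` differ in the last ulp for general `c`, so bit-identity of
scores holds exactly for power-of-two multipliers (exact rescalings) and to
~1e-15 relative error otherwise; predictions are identical in both regimes
and the test suite checks both.

## Threshold optimization

The decision cut is chosen by sorting the training scores and sweeping the
cumulative misclassification count over every cut position — the midpoints
between consecutive distinct scores plus −∞/+∞ sentinels — in both
directions, in one vectorised pass. This is exhaustive over all
behaviourally distinct (cut, direction) pairs, hence exactly optimal; the
test suite certifies equality with brute force on 1,000 random instances.
Ties on error are broken by the widest margin (largest gap between
neighbouring scores), then the smallest cut, then `score_greater`, making
the result deterministic. If all scores are equal, the sentinel cut with
error = min(class counts) is returned.

## Genetic-algorithm search

Learning optimal discrete-coefficient models is a subset-selection problem
that grows combinatorially, so the production path is a GA with one island
per model size `k` (sizes never mix inside an island; the penalized
selection afterwards compares sizes fairly). Defaults: population 200 per
island, 100 generations, elite fraction 0.1, mutation rate 0.2, crossover
rate 0.8, tournament size 2 — conventional settings, all configurable.

- **Initialization**: half of each island is seeded from the top
  Mann-Whitney-ranked features with signs set by class-wise enrichment
  (mean rank higher in the positive class → +1/numerator); the first
  seeded model is exactly the top-k ranked features. The rest are uniform
  random subsets with random signs.
- **Mutation** hits each selected feature independently with the mutation
  rate; Ter/Ratio positions choose 50/50 between a swap for an unselected
  feature and a sign/side flip, Bin positions always swap. Model size is
  preserved.
- **Crossover** draws child features (with their signs) from the union of
  the parents' features; conflicting signs take a side at random per child.
- **Elitism** carries the best models over unchanged, so the best-so-far
  fitness is non-decreasing — a tested invariant.

Every candidate's threshold is refit and fitted models are memoized by
canonical structure (fitting is deterministic given the data). All
randomness flows from one `SeedSequence`, so identical seeds give
bit-identical final populations. An exhaustive enumerator with a guard
bound (default 2×10⁶ evaluated models) serves as the optimality oracle on
small instances: at p = 12, n = 60, k ≤ 3 the GA at default budget reaches
the exhaustive penalized optimum in ≥ 95% of seeded runs.

## Model selection and the FBM

The selected model maximizes `fitness − λk` with λ = 0.01: one extra
feature must buy more than one accuracy point. Ties go to the smaller
model, then lexicographic feature names, so selection is invariant under
population reordering.

The family of best models (FBM) collects every searched model whose
training accuracy lies within a sampling-noise window of the best:
`window = z₍₁₋p₎ · sqrt(a(1−a)/n_train)` with `a` the best accuracy — a
one-sided normal approximation to the binomial, with an exact-binomial
quantile behind a flag (the two differ negligibly for n ≥ 30). Members are
deduplicated by feature/sign structure, ignoring the threshold. Note the
direction of the p-level: a smaller `p_level` yields a larger `z` and hence
a *wider* window (it is harder to call a difference significant), so the
family can only grow. The window is computed from training accuracy within
each fold; computing it from CV accuracy instead is a defensible
alternative we did not take (it would couple the window to the fold
geometry).

## Evaluation harness

Generalization is estimated by repeated stratified k-fold CV (10×10 for
classification by convention, 20×5 for regression), with every
data-dependent step — SD filtering, Mann-Whitney ranking, thresholds —
learned inside the training folds. Stratification is our choice (class
imbalance is the norm in case–control cohorts); absolute numbers from
unstratified schemes can differ slightly. Learners are compared by a
paired t-test over the per-split test metrics; p ≥ 0.05 means equivalent,
and zero-variance difference vectors short-circuit (all-zero → equivalent)
to avoid 0/0. Comparator learners are scikit-learn adapters: elastic-net
logistic regression (mixing 0.5), random forest (500 trees), linear SVM;
the ENET fixed-size variant takes the first k features to enter an
`enet_path` computed on a ±1-coded response — a linear surrogate for the
logistic path, which scikit-learn does not expose.

The SD filter drops features below the elbow of the sorted-SD curve, the
elbow being the maximum central second difference of SD against rank. The
curve is the *sorted* SD sequence, not a density estimate — an
interpretation we fix deliberately. The threshold is the first SD past the
elbow corner (this is the cut that separates a low-variance cluster from a
high-variance one); a flat curve filters nothing, SD = 0 features are
always dropped, and ties take the smallest threshold (retain more).

## Feature importance (MDA)

Importance is permutation-based mean decrease accuracy over the FBM: per
CV fold, one feature at a time is permuted across the fold's held-out
samples, each FBM model's held-out error is recomputed, and the error
increase is averaged over FBM models (models not containing the feature
contribute exactly 0) and permutations (default 10 per fold — a
cost/variance compromise), then over folds, with the SEM across folds.
Error is always 1 − accuracy regardless of the search metric. "Held out"
here means the CV test fold; an RF-style internal bootstrap would be the
other reading of out-of-bag, and the parameter names say which one this
is. Permuted matrices intentionally break per-sample closure; validation
is bypassed for them, as the perturbation is a measurement-destruction
device, not a dataset.

## FBM distillation

The models × features signed incidence table underlies two summaries:
per-feature prevalence/abundance-shift statistics (detection fraction
overall and per class, two-sided Mann-Whitney), and a feature co-presence
network whose edge weight is the phi coefficient of feature presence
across FBM models — positive for features that appear together
(complementary signal), negative for features that replace one another
(redundant signal). Only the strongest `top_fraction` (default 5%) of
edges by |weight| is kept. This association network deliberately replaces
a full consensus network-reconstruction stack: the interpretable quantity
(co-presence vs. replacement, and its inversion relative to the data-level
correlation) is preserved; edge directions are not. Degenerate
(constant-presence) features are excluded with a warning.

## Synthetic data

The generator emulates the statistical shape of shotgun relative-abundance
tables: per-feature log-normal abundances (log-means drawn with SD 1.5 —
orders of magnitude between rare and dominant features; within-feature
log-SD 1.0), zero-inflation by a detection quantile (30% zeros by
default), and per-sample closure to 1. Log-normal-plus-closure was chosen
over a Dirichlet because it controls per-feature location and dispersion
independently while producing heavy-tailed sparse profiles. Labels come
from a planted BTR model (cut at the score median unless given, which
balances classes) with independent flips at the label-noise rate (5%
default); continuous targets are affine in the planted score plus Gaussian
noise.

What it does **not** emulate: taxonomy and phylogenetic correlation,
batch/cohort effects, sequencing-depth artefacts, or the correlation
structure of real communities. Passing recovery tests therefore shows that
the search finds planted sparse signals under compositional noise — not
that it will match any particular real-cohort accuracy.

## Problem sizes used in tests and the acceptance script

Study conditions follow the generator defaults (n = 300, p = 100, 5%
label noise, planted k = 3) for recovery checks, with the GA at population
100 / 30 generations for the full fit and 64 / 20 inside the 3-fold CV
used for MDA ranking — budgets chosen once for single-CPU runs and kept
fixed. The GA-vs-oracle certification runs the full default budget
(200 × 100) on p = 12 / n = 60 instances where exhaustive enumeration is
exact. The null-safety check uses constant-feature data, where every
learner provably collapses to a majority-side rule, making the
baseline-equality invariant exact rather than approximate.

## Known limitations

- Binary classification only in the CV harness; regression is supported at
  the model level (score scaling by OLS) but not benchmarked end to end.
- The FBM window uses training accuracy, which is optimistically biased;
  the family should be read as "not distinguishable on the training data".
- Best-subset-style selection over many discrete models inflates apparent
  CV accuracy on small datasets with chance structure (a property of model
  selection, not a leak); compare against the majority baseline and the
  paired t-test rather than trusting absolute accuracy.
- The co-presence network is undirected association, not a causal or
  directed graph.
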