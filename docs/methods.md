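# Methods

`mlmetab` implements a multilevel (paired within-subject) metabolomics
analysis for arterial versus venous umbilical cord plasma, together with
between-subject trait models, permutation inference, and univariate
follow-up. This note records the model, its assumptions, the tunable
parameters that matter, and the design choices made where the design was
genuinely open.

## The multilevel model

A paired cord-blood study measures two plasma samples per newborn: one from
the umbilical artery (blood from the fetus) and one from the vein (blood
from the mother). Between-subject variation in the metabolome is typically
much larger than the arteriovenous difference, so the analysis first
removes it by forming the **effect matrix**

    e_ij = log2( arterial intensity_ij / venous intensity_ij )

for subject i and feature j. The effect matrix is stacked on top of its
negation, `X = [E; -E]`, with targets `y = (-1, ..., -1, +1, ..., +1)`:
classifying the sign of the within-subject contrast. The decision boundary
for the continuous forest predictions is at zero. The two mirrored rows of
a subject always share a group id and therefore a cross-validation fold.

Internally the engine collapses each mirrored pair to a canonical
orientation (the row whose first nonzero entry is positive). Training still
sees both orientations, but predictions are made once per pair and emitted
as `(p, -p)`. Two exact symmetries follow, and are asserted in tests:

* a subject's two rows always receive exactly opposite predictions;
* swapping the arterial/venous labels (which negates E) reproduces the same
  canonical problem with negated targets; regression trees are invariant to
  target negation up to leaf sign, so predictions and the classification
  rate are preserved bit for bit under the same seed.

## Repeated double cross-validation with variable elimination

The modeling engine (`RandomForestRdCV`) is a random-forest repeated double
CV in the MUVR tradition:

* `n_outer` outer folds (default 6) held out in turn, never touching model
  selection; folds are group-aware, and stratified by class for
  between-subject classification (systematic sampling over the sorted
  response for regression);
* an `n_inner`-fold inner CV (default `n_outer - 1`) on each outer-training
  set drives recursive variable elimination: variables are ranked by mean
  impurity importance across inner folds and `ceil(var_ratio * p)` survive
  each round (default `var_ratio = 0.75`, floor `min_features`);
* from the inner fitness-versus-count curve, the `min` and `max` model
  sizes are the smallest and largest counts within `fitness_tol` (default
  5%, relative) of the optimum; `mid` is the rounded geometric mean of the
  two, snapped to the nearest count on the elimination path;
* models of each size are refit on the outer-training set and predict the
  held-out fold; the whole procedure repeats `n_rep` times with fresh
  partitions, and each observation's final prediction is its average
  out-of-fold prediction across repetitions.

Classification is regression onto ±1 targets with the zero decision
boundary; a prediction of exactly zero counts as misclassified. Fitness is
the classification rate, or Q2 = 1 − PRESS/TSS for continuous responses,
both computed on averaged out-of-fold predictions. Reported headline
fitness and gate decisions use the mid-size model.

**Forest sizes are odd by default** (151 for primary fits). With ±1 targets
and fully grown trees, most leaves are pure, so an even forest can average
to exactly zero — a point mass on the decision boundary that drags the null
classification rate visibly below 1/2 under the "zero is wrong" rule. An
odd tree count removes the point mass; this matters mostly for small
repetition counts, since averaging across repetitions also breaks ties.

Elimination ranks are per-(repetition, outer fold) total orders: variables
dropped earlier rank worse, survivors are ordered by final importance; the
reported rank is the average. The selected set at each size is the most
frequently chosen variables across folds and repetitions (ties broken by
average rank, then stable feature order), truncated to the rounded mean
size.

## Permutation inference and the performance gate

Models are gated **a priori**: only Q2 > 0.2 or classification rate > 66%
(strict) proceed to permutation testing; failing models are reported as
null results and never permuted.

The permutation null respects the design. Multilevel designs are permuted
by independently flipping the sign of each subject's mirrored row pair —
the exchangeability-preserving analogue of swapping vessel labels within a
subject, since the generative roles of the two vessel errors are symmetric
under the null. Trait designs permute labels across subjects. P-values use
the add-one estimator `(1 + #{null >= observed}) / (1 + n_perm)`; the raw
proportion is reported alongside.

The observed statistic is recomputed inside the test by the same fit
function and seeding scheme as the null statistics, so all `n_perm + 1`
values are exchangeable under the null — this is what makes the type-I
error exact at achievable levels. Permutation refits use reduced settings
with Q2 as the statistic regardless of the primary fitness: a permutation
p-value is valid for any statistic, and Q2 is continuous, avoiding the
conservatism that ties in a coarse classification rate would introduce.
The pipeline's default refit (one repetition, three outer folds, halving
variable elimination down to five features, a 15-tree forest) keeps the
elimination step because without it the statistic loses power when the
informative features are a small fraction of hundreds — a diluted
three-tree forest cannot see 14 planted features among 416. The
calibration tests use an even cheaper non-eliminating refit, which is
fine there: calibration concerns the null, where power is irrelevant.
The cost of any reduced refit is some power relative to permuting the
full procedure; refit settings are configurable.

## Preprocessing

* **Tier merging** — MRM, targeted and untargeted feature tables are
  concatenated; explicitly provided equivalence links (never inferred from
  spectra) are resolved by union-find, keeping the copy from the most
  reliable tier (MRM > targeted > untargeted).
* **Pair validation** — a pair is kept only if arterial pH is strictly
  below venous pH; ties and inversions indicate sampling error and remove
  the pair. Missing pH excludes a pair separately from rule-based removal.
* **Imputation** — iterative low-rank completion on the log2 scale
  (defaults: 3 components, tol 1e-4, max 50 iterations): missing cells are
  initialized at feature medians, then alternately refit from a truncated
  SVD of the column-centered matrix. Observed cells are never modified.
  With the default missing rate (~0.026%) the imputed values are
  immaterial downstream; the method choice matters only for the exactness
  tests, which use a rank-1 scenario at one component (a higher rank can
  represent a single corrupted cell exactly and make no progress — a known
  property of hard-rank completion).
* **Batch alignment** — per feature, each batch's log2 intensities are
  shifted so the batch median matches the reference median, defined as the
  median *of the eligible per-batch medians* rather than the pooled median:
  this makes the operation exactly idempotent while removing the additive
  offsets the generator plants. Batches with fewer than 3 samples are left
  unshifted with a warning. Zero or negative intensities are converted to
  missing before any log transform.

## Univariate follow-up

Fold changes are geometric means of ratios — `2 ** mean(log2 ratio)` for the
paired arteriovenous contrast, ratio of group geometric means for traits —
coherent with the log2 effect matrix. Which group is the numerator is an
explicit argument, echoed in the output, never guessed. Mann-Whitney U
tests (exact null when the smaller sample has ≤ 8 observations and no ties,
normal approximation with tie correction otherwise) are the tabulated
p-values for both the arteriovenous table (vessels as two groups, the
convention of the corresponding published tables) and trait tables; the
paired one-sample t-test on effect-matrix columns is reported side by side
for the vessel contrast, since the two tests answer slightly different
questions for paired data. Benjamini-Hochberg step-up controls FDR within
each table (via statsmodels; an independent brute-force oracle checks it in
tests). t-tests run on the log2 scale; rank tests are scale-invariant.

Replication against a previously reported metabolite list tests each prior
metabolite at unadjusted α = 0.05 and requires the fold-change direction to
match; metabolites absent from the current data are reported as
"not measured" rather than failing.

## The synthetic-data generator

The generator emulates the study conditions: 48 subject pairs, 416 features
split 30/117/269 across tiers, 23/48 nulliparous mothers, four acquisition
batches, 0.026% missingness. All effects are additive on the log2 scale and
exponentiated:

* subject baseline `N(mu_j, sigma_between^2)` with `mu_j ~ U(10, 20)` —
  intensities span ~1e3–1e6 arbitrary units;
* planted arteriovenous effects: the 11 reported fold changes (0.71–1.72)
  as signed log2 shifts on arterial intensities;
* planted parity effects: the 14 reported fold changes (0.84–2.14) on
  venous intensities of nulliparous subjects only;
* additive per-(feature, batch) offsets `N(0, batch_sd^2)`, identical for
  both samples of a subject (pairs are acquired together);
* cord pH with arterial below venous by `|N(0.07, 0.02)|`, violators
  injected by swapping (the first violator is an exact tie);
* optional extra noise on "delayed" samples (bench time > 24 h before
  freezing), emulating pre-analytical degradation.

The variance components are assumptions, not estimates — the study does not
report them. Defaults are `sigma_between = 1.0` and `sigma_within = 0.52`
on the log2 scale: between-subject variation dominates, and the median
planted arteriovenous effect then has Cohen's d ≈ 0.6 on the log2-ratio
scale. What passing tests show is therefore that the pipeline recovers
effects of the reported magnitudes *under this noise model*; real data add
structure the generator deliberately omits (correlated features,
intensity-dependent missingness, within-batch drift, non-normal tails), so
synthetic recovery rates do not transfer to cohort data as-is.

A consequence worth knowing: with 48 subjects and ~100+ features, a
between-subject model of a null vessel occasionally finds genuinely
predictive chance associations (a feature whose subject-level variation
happens to align with the trait split reaches |t| ≈ 4 now and then). This
within-cohort confounding is real signal for cross-validation — it cannot
be averaged away — and is the expected reason a null-vessel model sometimes
approaches the 66% gate, mirroring how a real arterial model can sit above
50% without clearing the gate.

## Problem sizes for desk-scale verification

The test suite and the acceptance script run reduced problem sizes chosen
once and fixed: calibration of the permutation test uses 200 null studies
of 48 × 100 with 99 permutations each under the reduced permutation
settings above; planted-effect recovery uses 10 seeds at 48 × 100 with
moderate engine settings (2 repetitions, 5 outer folds, `var_ratio` 0.6,
31 trees); trait asymmetry uses stronger averaging (4 repetitions, 6 outer
folds, 3 inner folds, `var_ratio` 0.5, 31 trees) because the venous parity signal
sits near the gate by construction. The acceptance script runs the full
416-feature study once, end to end, at the moderate settings.

## Known limitations

* The trait-model gate at 48 subjects is a noisy decision: the venous
  parity classification rate fluctuates around ~0.75 across synthetic
  cohorts, so individual cohorts can fail the gate even though the median
  clears it; the arterial model can conversely pass by chance confounding.
  This is a property of the study size, not of the estimator.
* Permutation refits at reduced settings trade power for feasibility at
  n_perm = 1000; the refit settings are configurable.
* The imputer is a generic low-rank completer, not the (unpublished)
  original algorithm; at the study's missingness level the difference is
  irrelevant downstream.
* Batch correction removes additive per-(feature, batch) offsets only — no
  within-batch drift modeling.
* Pathway analysis is out of scope.
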