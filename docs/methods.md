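# Methods

## Problem and model

`methclass` classifies pediatric brain-tumor samples into nine entities
(DIPG, ependymoma, ETMR, glioblastoma, the four medulloblastoma subgroups
MB_Gr3/MB_Gr4/MB_SHH/MB_WNT, and pilocytic astrocytoma) from 450K-array
DNA-methylation beta values. The model is a two-stage pipeline: univariate
one-vs-rest screening reduces ~10^5 probes to a panel of ≤ 100 probes per
class, and a random forest over the panel produces per-class vote-fraction
probabilities. The pipeline assumes processed beta values in [0, 1]
(IDAT processing, normalization and probe-type correction are upstream and
out of scope), assumes classes are defined by a labeled training cohort,
and applies no cross-study batch correction after merging — merged studies
are used as-is, matching the upstream design where datasets are merged on
their common probe set and filtered against a CpG blacklist.

## Probe screening

Each probe is scored per class by the probability that a random in-class
beta exceeds a random out-of-class beta (ties counted half) — the AUC or
c-statistic — computed via the Mann–Whitney rank-sum identity. Because the
AUC is invariant under strictly monotone transforms, this equals the AUC
of a single-covariate logistic regression on the probe while avoiding
~10^6 model fits. Scores are folded to max(a, 1 − a), so hypo-methylated
markers rank as highly as hyper-methylated ones; the recorded `direction`
(hyper/hypo) replaces the regression coefficient's sign. Ranking ties are
broken by probe ID so rankings are platform-independent. Per-class lists
are truncated to `n_per_class` (default 100) and merged, deduplicating
probes selected by several classes (the overlap count is logged).

## Imputation

Missing betas are filled by k-nearest-neighbor imputation in probe space,
the microarray KNNimpute convention: the distance between two probes is
the Euclidean distance over their mutually observed samples divided by
sqrt of the shared-sample count; donors for a cell must be observed at
that sample; values are combined with inverse-distance weights guarded at
1e-12, falling back to a plain mean on exact distance ties. Probes missing
more than `max_missing_fraction` (default 0.5) of their samples are
dropped; fewer than k usable donors is a hard error rather than a silent
fallback. Defaults k = 10. Imputed values are convex combinations of
observed betas and therefore stay in [0, 1]. On large matrices the
pairwise distances are computed from a dense Gram matrix plus sparse
corrections for the missing entries, in single precision (the computation
is memory-bandwidth bound); small matrices use an exact double-precision
direct path. Neighbor order is unaffected except for ties far below data
resolution.

## Forest

The forest is scikit-learn's `RandomForestClassifier` (CART trees, Gini
impurity, grown to purity, bootstrap resamples of size n with
replacement), with two deliberate departures from its stock outputs:

- **Probabilities are exact hard-vote fractions.** Each tree votes one
  class; the probability of class k is (votes for k)/(n_trees), never
  scikit-learn's averaged leaf proportions. Vote counts are integers
  summing to n_trees, so reported probabilities are exact multiples of
  1/n_trees.
- **OOB statistics from bootstrap membership.** Out-of-bag predictions
  are majority votes over only those trees whose bootstrap excluded the
  sample, reconstructed from per-tree bootstrap indices. Argmax ties
  resolve to the first class in sorted order.

Defaults: 900 trees; `mtry` (predictors considered per split) grid-searched
over {⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋, ⌊p/10⌋, ⌊p/3⌋} (deduplicated, clipped to
[1, p]) maximizing OOB kappa, ties to the smallest value; no class
reweighting. A sample's call is its majority class when the winning vote
fraction reaches `call_threshold`, else `inconclusive`. The default
threshold 0.40 sits between published confident calls made at 0.49 and
withheld ("mixed") calls at 0.32; it is a documented package choice, not a
value taken from a publication, and raising it can only withhold calls,
never flip one class to another. Classes are ordered lexicographically
everywhere (reports, probability columns, tie-breaks) for diffability.

## Evaluation

Cohen's kappa κ = (p_o − p_e)/(1 − p_e) corrects observed accuracy for the
chance agreement implied by the table marginals; its CI uses the
large-sample standard error se = sqrt(p_o(1 − p_o)/(n(1 − p_e)²))
(Fleiss–Cohen–Everitt) with z = 1.96, unit-tested against a hand-worked
2×2 table and cross-checked against an independent implementation.
Cross-validation is stratified by class with a seeded shuffle (repeat r
uses seed + r), defaults 10 folds × 5 repeats; probe selection and mtry
tuning run inside every training fold, so the pooled estimate carries no
selection leakage. A `leaky` switch selects once on the full data before
splitting, to measure that bias explicitly. Inconclusive calls are
tabulated in a separate confusion column and excluded from kappa and the
error rate by default; a strict mode counts them as errors.

## Synthetic cohorts

The generator emulates the merged multi-study design: 9 classes × 20
samples, 5,000 probes, 50 disjoint marker probes per class (alternating
hyper/hypo), 1% missing cells. Betas are Beta-distributed — background
Beta(5, 5), hyper markers Beta(8, 2), hypo markers Beta(2, 8) — keeping
values in [0, 1] by construction and giving per-marker population AUC
≈ 0.94 at 20-vs-160 samples. Heterogeneity h for a class (default 0.3 for
the GBM-like class, reflecting that glioblastomas are the most
heterogeneous entity) replaces each in-class marker cell by a background
draw independently with probability h; per-cell rather than per-sample
dilution was chosen because it shrinks the class's effective per-probe
AUC continuously toward 0.5 (a → 0.5 + (1 − h)(a − 0.5)) instead of
splitting the class into a bimodal mixture.

What the generator does **not** emulate: probe-probe correlation (CpG
islands), batch effects between studies, class imbalance, bimodal
background betas, or probes informative for several classes (marker sets
are disjoint by construction; the panel-overlap code path is exercised by
dedicated fixtures instead). Passing tests therefore demonstrate the
pipeline's correctness and its behavior under the modeled effect sizes —
not the published accuracy on real cohorts, which depends on cohorts that
cannot be bundled here.

Two consequences of the generator's design are worth stating plainly,
because the test suite measures them:

- With 50 true markers and 100 selected probes per class, half of each
  panel is necessarily null probes; their empirical folded AUC at n = 20
  vs 160 tops out near 0.75. The published "all selected sites above 0.9"
  floor is therefore *not* reproduced at these conditions — the floor
  check in `auc_summary` flags every class even on a perfectly separable
  cohort, and distinguishes signal from permuted-label noise by the upper
  half of the AUC distribution rather than its minimum.
- Diluting one class toward the common background does not degrade forest
  accuracy at moderate h: because marker sets are disjoint, a diluted
  sample's "no signature anywhere" profile is itself class-unique and
  learnable, and measured OOB error for the diluted class stays ~0 at
  h ≤ 0.6 (it rises only once selection itself collapses, h → 1).
  Heterogeneity-as-background-dilution raises the *number of probes
  needed*, not the error, at this scale.

## Problem sizes and numerical choices

The default synthetic scale (5,000 probes, 180 samples) keeps a full
pipeline run under a minute on one core; the 206,823-probe scale of real
merged cohorts is reachable through the same code paths but is not
exercised by the tests. The bundled end-to-end validation runs 5-fold × 2
CV with in-fold probe selection and the forest's mtry fixed at the
full-data grid-search optimum; per-fold mtry grids are the library
default but are several-fold slower at 900 trees. All randomness (cohort
draw, missingness mask, bootstraps, fold shuffles) derives from explicit
integer seeds; two runs with the same seed produce byte-identical
reports, and a serialization round trip reproduces probabilities
bit-for-bit, with a format-version string checked on load.

## Limitations

- Single-sample classification works for prediction, but kNN imputation
  needs multiple samples sharing observed probes; a lone sample with
  missing panel probes cannot be imputed in probe space.
- Vote fractions are not calibrated posterior probabilities; the call
  threshold trades coverage against confidence but does not change ranks.
- The kappa CI is the large-sample approximation; it degenerates (zero
  width) on perfect tables.
- No batch correction: systematic study effects in merged training data
  will be learned as if biological.
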