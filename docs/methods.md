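# Methods

## Problem setting

In multi-label classification each instance carries a subset of q labels
(gene functions, document topics, clinical codes).  Filter feature selection
ranks the d features by a criterion computed from the data alone, before and
independently of any classifier.  The information-theoretic family scores a
candidate feature f against the label set L and the already-selected subset
S, and grows S greedily (sequential forward selection): at every step the
candidate maximizing the criterion J(f) joins S.

The ideal relevance quantity I(S; L) — mutual information between the whole
feature subset and the whole label set — is not estimable at realistic
sample sizes, so practical criteria decompose it into low-order terms.  The
widely used decomposition is *cumulative summation*: relevance is
`Rel(f) = Σ_l I(f; l)` (or a double sum of per-label-pair terms).  This
implicitly treats labels as independent.  Real label sets are not: labels
cluster into *semantic groups* of near-synonyms ("Athletics", "Gymnastics",
"Swimming" ≈ "Sports") with high within-group and low between-group
dependence.  Under cumulative summation a feature informative for one large
group collects its contribution once per member label, so large groups
dominate the ranking, features for small groups are starved out, and the
selected set is redundant.

## Max-correlation selection

The max-correlation (MC) relevance term replaces the sum by a maximum:

    MC(f; L) = max_{C_i} max_{l ∈ C_i} I(f; l) = max_{l ∈ L} I(f; l).

Because a maximum over a partition of maxima collapses to a global maximum,
the criterion never needs to know the grouping — a decisive practical
advantage, since semantic groups are rarely annotated.  A feature's score is
the strongest single-label association it has, independent of how many
labels echo the same underlying concept.  The greedy objective (MCMFS) adds
a mean-redundancy penalty against the selected set:

    J(f) = MC(f; L) − (1/|S|) Σ_{f_j ∈ S} I(f; f_j),

with the first feature chosen by MC alone.  The 1/|S| factor keeps the two
terms on comparable scales as S grows.  This is the multi-label analogue of
mRMR: same redundancy term, but relevance aggregated by max over labels
rather than measured against a single target.

All information quantities are plug-in (maximum-likelihood) estimates from
empirical contingency tables, in bits (log base 2), with 0·log 0 := 0 and
no smoothing — smoothing would shift the small-sample label-dependence
values the fixture tests pin down.  MI and conditional MI are clamped at
zero (non-negative in exact arithmetic); interaction information is signed
and never clamped.  Pairwise terms are cached within a selector run; caching
is a pure speedup and cannot change values.

## Baseline criteria

Five published cumulative-summation criteria are implemented under the same
greedy interface, exactly as their printed formulas:

| method | J(f) |
|---|---|
| D2F  | Σ_l I(f;l) − Σ_{f_j∈S} Σ_l I(f;f_j;l) |
| SCLS | Σ_l I(f;l) − (Σ_{f_j∈S} I(f;f_j) / H(f)) · Σ_l I(f;l) |
| MDMR | Σ_l I(f;l) − (1/|S|) Σ_{f_j∈S} ( I(f;f_j) − Σ_l I(f;l|f_j) ) |
| PMU  | Σ_l I(f;l) − Σ_{f_j∈S} Σ_l I(f;f_j;l) − Σ_{pairs} I(f;l_i;l_j) |
| LRFS | Σ_{l_i} ( Σ_{l_j≠l_i} I(f;l_j|l_i) − (1/|S|) Σ_{f_j∈S} I(f;f_j) ) |

Conventions that the printed formulas leave open, and how they were fixed:

- **Empty S.**  All redundancy terms are defined as 0 at the first step
  (empty-sum convention; the 1/|S| normalizers never divide by zero).
- **SCLS with H(f) = 0.**  A constant feature has zero entropy and zero
  relevance; its score is defined as 0 rather than dividing by zero.
- **PMU label-pair sum.**  The double sum over label pairs excludes the
  diagonal (I(f;l;l) degenerates to I(f;l)) and, by default, counts each
  unordered pair once.  The unordered convention reproduces the published
  ranking of the reference artificial dataset exactly; the ordered
  convention (both directions, doubling the term) is available via
  `label_pairs="ordered"` and reshuffles the middle ranks.
- **LRFS.**  Implemented literally as printed, with the redundancy term
  inside the outer label sum — hence effectively weighted by q relative to
  the relevance term.  This differs from the original LRFS publication; the
  printed form is treated as authoritative here.
- **Tie-breaking.**  Everywhere, the lowest feature index wins (a plain
  argmax scan), making every selector fully deterministic.

The problem-transformation baselines (PPT + MI, PPT + χ²) map the label
matrix to a single multi-class target by label powerset, drop instances
whose label combination occurs fewer than `min_count` times (default 6 — a
common choice in the transformation literature; no canonical value exists),
and rank features univariately by MI or by the Pearson χ² statistic of the
feature × class contingency table (no continuity correction; degenerate
1×k tables score 0).

## Complexity

With the (d × q) feature–label MI table computed once and redundancy terms
accumulated incrementally, MCMFS and SCLS cost O(ndq + bnd) for b selected
features over n instances; D2F and MDMR add a per-label factor to each
redundancy update, O(ndq + bndq); PMU additionally precomputes the
label-pair interaction table, O(ndq + bndq + ndq²); LRFS front-loads its
conditional-relevance table, O(ndq² + bnd).  These are characterizations of
the implementation, not runtime assertions.

## Evaluation protocol

Continuous features are discretized by equal-width binning into three bins.
Bin edges for range [a, b] are a + i(b−a)/bins; intervals are left-closed,
right-open with the last closed; constant columns map to code 0.  For
train/test experiments the discretizer is fitted on the training split only
and applied to the test split (out-of-range values clamp to the outer
bins); fitting on the union is available (`fit_on="all"` semantics via
fitting the discretizer yourself) but train-only fitting is the default to
avoid information leakage — the choice is immaterial for already-binary
data.

Selection runs once per method at the largest requested budget; the curve
over the budget grid b = 1..⌈0.2·d⌉ is obtained by prefix slicing, which is
exact for sequential-forward selectors.  Classifiers:

- **ML-kNN** (K = 10, Laplace smoothing s = 1): per-label Bayesian
  posterior over the count of positive neighbours among the K nearest
  training instances; the posterior is the confidence score.
- **kNN** (k = 3): per-label neighbour vote; vote fraction as confidence.
- **Linear SVM**: one binary LinearSVC per label (binary relevance);
  signed decision value as confidence.  A label constant in training gets
  a constant predictor with confidence ±1.

K or k larger than the available training set is clamped with a logged
warning.  Metrics: Hamming loss (mean per-cell disagreement), zero-one loss
(top-confidence label not in the true set; argmax ties break to the lowest
label index; an instance with an empty true set counts as an error),
macro-F1 and micro-F1 (per-label F1 with 0/0 := 0 by default, a
`skip_undefined` flag averages only over defined labels instead).
Cross-validation uses seeded shuffled folds (default seed 0) with selection
repeated inside each training fold; reported values are fold means.

## Synthetic generator

The generator operationalizes the semantic-group assumption with the
simplest latent-factor model exhibiting it.  Per instance, each group g
draws a hidden factor z_g ~ Bernoulli(1/2); each of the group's labels
copies z_g flipped with probability `label_flip_prob · (1 − coupling)`;
each of the group's informative features copies z_g flipped with
probability `label_flip_prob`; noise features are independent fair coins.
Defaults — n = 2000 instances, group sizes (9, 1) (a ten-label set split
9-to-1, the scaled-down form of the 90/10 thought experiment), 3
informative features per group, 4 noise features, flip probability 0.1,
coupling 0.8 — give strongly block-structured label dependence with
realistic feature noise.

What the generator emulates: imbalanced label groups, within-group label
exchangeability, redundant informative features, irrelevant features.  What
it does not: overlapping groups, label-specific features within a group,
continuous features, skewed label priors, instance-dependent noise.  Tests
passing on this model therefore demonstrate the selector-level mechanism
(cumulative summation concentrates on the large group; max-correlation
spreads across groups) — they do not certify classification gains on any
particular real dataset.

## Reference artificial dataset

A 10-instance, 8-binary-feature, 5-label dataset is embedded as a fixture.
Its label MI matrix is block-structured into three groups {l1,l2,l3}, {l4},
{l5} (within-group MI 0.256 bits, cross-group ≤ 0.006).  All six greedy
selectors reproduce their published rankings on it exactly under the
defaults above; per-step scores are verified against a brute-force
recomputation that enumerates full joint tables.

## Known limitations

- Cross-validating the 10-instance fixture is noise-dominated: test folds
  have 2 instances and ML-kNN's K clamps to 7 = n_train − 1, at which point
  the neighbour-count statistic degenerates (leave-one-out training counts
  anti-correlate with test-time counts) and predictions invert.  The
  fixture's CV metrics are therefore reported but carry no reliable method
  ordering; the ranking-level and group-coverage results are the
  informative ones at this scale.
- Plug-in MI estimates are biased upward at small n; no bias correction is
  applied by design (see above).
- PPT's `min_count` default is a literature convention, not a fitted value;
  at tiny n it can prune aggressively (the transform errors if nothing
  survives).
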