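# Methods

## Problem and data model

The unit of analysis is an outpatient prescription reduced to drug-group
counts: with G pharmacological groups, prescription *i* is a vector
x_i ∈ ℕ^G where cell g counts the (drug, group) incidences — a drug
belonging to two groups contributes to both, and two drugs of one group
make the cell 2. Each prescription carries one disease label in 1..K,
where class K is a catch-all for the diseases not modelled individually.
Grouping (hundreds of drugs into a few dozen groups) is what keeps the
feature space tractable at a sample size of order 10³; the encoding module
assumes the drug→group mapping is given and exact (no name normalization).

## Shared-group baseline

Domain knowledge enters as a binary K × G disease-signature table: row *j*
marks the c_j drug groups characteristic of disease *j*. A prescription
with b_i distinct groups, sharing a_ij groups with disease *j* (supports
intersected as sets — counts of 2 add nothing), scores

    m_ij = a_ij / sqrt(b_i * c_j),

and is tagged with argmax_j m_ij. The square-root normalization is the
cosine similarity of the two binary supports: it is the reading of
"normalize the shared counts" consistent with m ∈ [0, 1], with m = 1
exactly when prescription support and signature coincide, and with
diseases of different signature sizes being comparable. "Tag with the
largest average" is read as "largest normalized score", since the scoring
yields one number per (prescription, disease). Both readings are
interpretations made here and are the package's fixed convention.

Ties (including the degenerate all-zero-score row) resolve to the lowest
class index; tie and zero-score events are counted on the classifier
(`tie_count_`, `zero_score_count_`) and logged, so audits can see how often
the deterministic rule actually fired.

## Base classifiers

Six learners run under one contract (`make_spec` → `fit` → `predict`),
with established scikit-learn implementations behind it. The configured
defaults, and where a named knob had no exact counterpart, the mapping:

| learner | defaults | notes |
|---|---|---|
| decision_tree | entropy criterion, min leaf 1, ccp_alpha 0 | the C4.5-style confidence factor 0.55 governs post-pruning; values ≥ 0.5 prune essentially nothing, so the tree is grown unpruned |
| svm | polynomial kernel, C = 1.6, degree 3, gamma "scale" | kernel degree is unstated upstream; 3 is this package's documented choice. Multiclass is one-vs-one with pairwise coupling (the implementation's native scheme) |
| neural_net | one hidden layer of 63 units, SGD, lr 0.3, momentum 0.2, exactly 500 epochs | convergence-based stopping disabled (`n_iter_no_change` = epoch budget) so the full 500 steps always run |
| naive_bayes | Gaussian likelihoods | counts 0/1/2 violate the Gaussian assumption; this learner is expected to be the weakest on noisy data, and is kept as configured |
| logistic_ridge | ridge factor 10 → C = 0.1, L2 | multinomial |
| knn | k = 1, Manhattan distance | |

All estimators that accept a random state receive the spec seed, so fixed
seeds give identical cross-validated predictions.

## Combiners

**Weighted voting.** Every classifier starts at weight 1; each training
error multiplies its weight by the updating rate β ∈ (0, 1], giving the
closed form w_j = β^(e_j). β = 1 assigns everyone the same weight and is
*exactly* plain majority voting — an identity asserted property-wise in the
tests. A row's winner maximizes the summed weight of its voters; ties go
first to the class backed by the single heaviest voter, then to the lowest
class index, and are logged. Weights are deliberately not normalized
(argmax is scale-invariant).

Error counts are taken from out-of-fold predictions, not resubstitution,
so a learner that memorizes the training set is not rewarded with a
perfect weight; a `weight_mode="resubstitution"` flag exists for fidelity
experiments. Whether the original analysis used held-out or resubstitution
errors is unknown; out-of-fold is the defensible default.

**β search.** Candidates 0.10…1.00 in steps of 0.01 are scored by
cross-validated weighted-vote accuracy, weights learned on the training
folds only; exact ties resolve to the largest β (least aggressive
down-weighting).

**Stacking.** A J-fold split; for each fold the N base learners train on
the complement and predict the fold, producing an n × (N+1) meta-dataset
(N predicted labels + actual class) in which no row was predicted by a
model that trained on it — the `MetaDataset` records the training rows per
fold and `assert_no_leakage()` re-checks the separation structurally. The
second layer is 3-NN. Predicted labels are categorical, so the meta-learner
sees them one-hot encoded: nearest-neighbour distance then counts label
disagreements (Hamming-like) instead of imposing a spurious ordering on
class indices. Both the one-hot choice and the distance are interpretations
documented here, since the upstream description fixes neither.

**Fold-aligned ensemble evaluation.** One out-of-fold prediction matrix
(J = the evaluation folds) serves every combiner: for test fold j, vote
weights and the stacking meta-learner are learned from the rows of the
other folds, whose predictions come from models not trained on them, and
applied to fold j's rows. This keeps each base learner at J fits total
(instead of J·(J+1) for nested refitting) while preserving train/test
separation for the quantity being reported. The error counts feeding the
weights are produced by models whose training folds overlap other rows of
the training side — the standard, mild reuse that stacked generalization
itself relies on.

## Evaluation

Stratified K-fold (default 10) with out-of-fold predictions pooled into a
single confusion matrix per method; accuracy = 100·trace/n. Per-class
metrics are one-vs-rest: sensitivity 100·TP/(TP+FN), specificity
100·TN/(TN+FP), precision 100·TP/(TP+FP). Undefined ratios (e.g. precision
of a never-predicted class) are reported as not-available (NaN), never 0,
and macro averages skip them. Stratification is used because classes with
a handful of members would otherwise vanish from folds; pooling (rather
than per-fold averaging) matches reporting one confusion matrix per
method. Percentages print with one decimal.

## Synthetic study conditions

The generator emulates the structure of a real prescription table without
modelling pharmacology (no drug names, ATC codes or dosages). Its
canonical conditions (`default_config`) are: n = 1412 prescriptions,
K = 11 classes, G = 60 groups; per-class signature sizes
[4, 3, 3, 3, 3, 3, 3, 3, 1, 1, 6]; the asthma-like class 1 shares 2 of its
4 groups with the catch-all class 11; the catch-all's 6 groups split into
3 sub-signatures of 2 (a prescription draws on one of them), making it
heterogeneous the way a "remaining diseases" class is; classes 9 and 10
have single-group signatures, mimicking diseases treated with one specific
medication. 75% of prescriptions carry 1–2 unrelated drug groups ("noise"),
each signature group independently holds a duplicated drug with
probability 0.2, and prevalences are skewed with 30% of rows in the
catch-all. The noise level and prescription-length distribution of real
data are uncharacterized upstream; these values are fixed, field-plausible
choices, not estimates of any particular registry.

Generation is one seeded `numpy.random.Generator` stream: signature groups
come from a random permutation of 1..G with overlap requests carved out
first (exact constraint satisfaction), remaining assignments disjoint;
noise groups are drawn uniformly off-signature without replacement;
infeasible demands (more distinct groups than G, overlap larger than a
signature) raise a configuration error before any sampling.

Two derived condition sets are fixed in code: `separable_config`
(disjoint signatures, no noise — every method should be at or near 100%)
and `overlap_scenario_config`, which isolates the overlap-confusion
pattern. The latter keeps a single one-group class and exactly one noise
drug per noisy prescription, because the degenerate score arithmetic
otherwise blurs the pattern being isolated: with two noise drugs, a pair
landing in one three-group signature scores 2/√(3·3) ≈ 0.67 and outscores
the true single-group class's 1/√(3·1) ≈ 0.58, and a second one-group
class creates exact ties that the lowest-index rule resolves against the
higher index.

What passing on these data does and does not show: the generator's
classes are conditionally independent given the label and its noise is
uniform, so results here demonstrate the pipeline's correctness and its
qualitative behaviour (baseline degraded by shared signatures, learners
robust to moderate noise, combiners at least as good as the best base
learner) — not the absolute accuracies attainable on real prescriptions,
where drug co-occurrence, prescriber habits and stage-dependent regimens
violate those simplifications.

## Problem sizes and numerics

Test and script workloads are sized for a single CPU: the full experiment
runs at n = 1412 with 10 folds (the neural network, at 500 epochs × 10
fits, dominates and completes in well under a minute); exact-recovery
checks use n = 1100; the noise sweep averages 5 seeds at n = 2000.
Floating-point comparisons in the voting path use a 1e-9 relative
tolerance when detecting score ties; weight equality is asserted to 1e-12;
the chi-square check on label prevalences uses α = 0.001 at n = 10 000.
All label sets are 1-based integers end to end.

## Known limitations

- The drug→group mapping is taken as given; no fuzzy matching of drug
  names.
- Hard-label combining only: no probability averaging, no ROC/AUC.
- The Gaussian naive Bayes learner is a poor model for count features and
  underperforms markedly on noisy synthetic data; it is retained as part
  of the configured bank rather than silently swapped for a multinomial
  variant.
- The catch-all class's heterogeneity means very small samples can leave a
  sub-signature unrepresented in a training fold; exact-recovery tests use
  either homogeneous classes or sample sizes large enough to rule this out.
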