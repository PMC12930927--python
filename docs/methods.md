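# Methods

This note documents the models, the synthetic-data generating process, the
numerical choices, and what the test suite does and does not establish.

## Federated ordinary least squares

For sites k = 1…K with intercept-augmented designs X_k and outcomes y_k,
the pooled OLS solution solves (Σ_k X_kᵀX_k) β = Σ_k X_kᵀy_k. Each client
therefore communicates only its sufficient statistics (X_kᵀX_k, X_kᵀy_k,
n_k); the aggregator sums them and solves the normal equations once. This
federation is *exact*: the result equals pooled-data OLS for every
partition, which the suite verifies over random datasets and partitions
into 1–10 sites.

**Secure aggregation.** The statistics are summed under additive secret
sharing over the ring ℤ₂⁶⁴ with fixed-point encoding at scale 2¹⁶
(precision ≈ 1.5·10⁻⁵ per entry). A client splits its encoded tensor into
K shares — K−1 uniform over the ring, the last the encoded value minus
their ring sum — so the element-wise ring sum over all shares of all
clients decodes to the exact fixed-point total while any proper subset of
shares is marginally uniform. The scheme is chosen for exactness of sums;
it models the honest-but-curious aggregator and does not handle dropouts
or malicious parties.

**Degenerate designs.** If the aggregated XᵀX is rank deficient (smallest
eigenvalue ≤ 10⁻¹⁰ of the largest) the solver fails with an error naming
the rank, because silent regularization would break the exact-equivalence
property. An explicit `ridge=True` flag adds a jitter of 10⁻⁸·trace/p to
the diagonal for users who prefer a solution over an error.

## Federated random forests

Clients train standard scikit-learn random forests (bootstrap + random
feature subsets) on their local rows. The total tree budget is divided
equally across clients by default (size-proportional allocation is
available) so that the pooled ensemble has the same number of trees as the
centralized forest it is compared with; provenance for the comparison is
kept by tagging every tree with its client of origin. Aggregation is
concatenation; prediction is the mean of tree outputs for regression and
the mean of per-tree class-probability vectors (soft voting) for
classification, which provides the threshold-free scores needed for
AUROC/AUPRC. A `rounds` knob splits each client's budget across several
contribution rounds; the default is one-shot pooling, since nothing in the
ensemble is gradient-trained and iterating adds no information.

**Differential privacy.** Released trees are protected by output
perturbation with the Gaussian mechanism, σ = Δ·√(2 ln(1.25/δ))/ε
(valid for ε ≤ 1; defaults ε = 1, δ = 10⁻⁵):

* regression — leaf predicted values are clipped to the outcome range
  [−100, 100] and noised with sensitivity Δ = range width / smallest leaf
  size in the tree (one record moves a leaf mean by at most that much);
* classification — leaf class-count vectors are noised with Δ = 1, floored
  at zero and renormalized to proportions.

Split structure is *not* privatized; only leaf statistics are. This is an
interpretation — output perturbation is the simplest mechanism consistent
with "trees shared under (ε, δ)-DP" — and it makes the privacy/utility
trade-off legible: noise per leaf is Δ·4.84 at ε = 1, so leaf sizes must
be large enough to carry signal. For that reason the DP study
configurations enforce leaves of ≥ 25 samples; with 5-sample leaves the
classification noise (σ ≈ 4.8 on counts of ~5) drowns the votes, which is
visible as a federated accuracy drop in exploratory runs.

## Evaluation protocol

Per-site 5-fold cross-validation with a single shared fold plan: within a
fold, local models train on their own site's training split, the
centralized model on the concatenation, the federated model on the
distributed splits — and *all* models are scored on the same merged test
rows. For the imbalanced classification task, each site's training split
is first supersampled to class balance (minority rows duplicated by
sampling with replacement; originals kept); folds are stratified by label
so small sites cannot lose a class; and the merged test split is carved
into four balanced subsets whose majority-class draws are mutually
exclusive, each scored separately. Metrics: R² and RMSE for regression;
accuracy, AUROC, F1 and AUPRC for classification.

The three study hypotheses are one-sided Welch t-tests on per-(fold,
test-subset) values, with the local scenario summarized as the unweighted
mean across sites within each cell first (the natural reading of "average
of the local models"; sites are analysis units, not samples). For
classification this pools all k·4 = 20 values per scenario. Lower-is-better
metrics flip the test direction and the sign of the relative-improvement
column, so positive improvement always means "federated better". No
multiplicity correction is applied across metrics; raw p-values are
reported with the conventional star thresholds 0.05/0.01/0.001. When
federated and centralized values are identical in every cell (exact OLS
federation), the comparison returns p = 0.5 as the no-evidence value
rather than an undefined statistic.

The subsampling ladder re-runs the identical study with every site's
training split subsampled to a fraction of its size (default
1.0/0.75/0.5/0.25/0.1), leaving fold plans and test data untouched, and
reports the centralized-minus-local gap per fraction.

## Heterogeneity diagnostics

Per variable (ordinal variables treated as numeric, target included):
one-way ANOVA; Scheffé post-hoc pairs, with pair statistic
(x̄ᵢ−x̄ⱼ)²/(MSW·(1/nᵢ+1/nⱼ)) referred to (k−1)·F(α; k−1, N−k) and adjusted
p-value F̄ = statistic/(k−1) under F(k−1, N−k); and pooled-SD Cohen's D
(not Glass's Δ — the sites play symmetric roles). Scheffé controls the
family-wise error within each variable; no correction is applied across
variables, since the intended output is a per-variable screening map.
Variables constant across all sites are flagged and skipped; analyses are
on the raw scale (ANOVA and D are location/scale-equivariant, so z-scoring
would change nothing).

## Attribution

Linear models: exact Shapley values in closed form, φⱼ(x) = βⱼ(xⱼ − μⱼ)
with μ the background (training) mean; base value = mean prediction on the
background. Forests: exact path-dependent tree Shapley values computed by
the polynomial-time path-weight algorithm, with absent features
marginalized by the trees' own training cover (node sample weights), so no
separate background sample is needed; the interventional variant is out of
scope. Both satisfy local accuracy per sample (attributions + base =
prediction, tolerance 10⁻⁶; exact in practice), which the suite checks
against a brute-force subset-enumeration oracle on small trees. A model's
importance profile is the mean of absolute attributions over a test set;
federated/centralized agreement is summarized as top-k set overlap and
order identity (k = 5). For classification forests the attributed output
is the positive-class probability. The implementation is numba-compiled
with a pure-Python fallback.

## Synthetic data generating process

Every feature derives from a standard-normal latent variable plus a
per-site mean shift expressed directly on the Cohen's-D scale. Continuous
features are the latent values; ordinal features are discretized at
equal-probability normal quantiles into L integer codes (population
variance (L²−1)/12); binary features threshold at zero. Features are
independent — real survey items are correlated, so the presets probe
site-shift heterogeneity, not collinearity structure.

Regression outcome: y = intercept + X·β + site offset + N(0, σ²), clipped
to [−100, 100] (the natural bounds of a 0–100 visual-analogue-scale change
score; clipping-induced bias is accepted and negligible at the calibrated
scale, outcome SD ≈ 22). σ² is set in closed form from the intended
population R² of the linear signal: σ² = Var(X·β)(1−R²)/R², with Var(X·β)
= Σ βⱼ²Var(xⱼ) analytic for each encoding. With β = 0 no σ can attain a
positive R², so the generator falls back to unit noise.

Classification outcome: y ~ Bernoulli(expit(X·β + a)) with a solved per
site (Brent root-finding on the sampled scores) so the expected positive
fraction equals the site's configured prevalence.

**Preset calibration.** The five-region preset uses β sparse with five
dominant coefficients (8/6/5/4.5/4 on continuous features, remainder
±0.3) — giving the attribution checks a planted ground truth — scaled so
pooled OLS lands at R² ≈ 0.32–0.34 and RMSE ≈ 18, the regime of the
registry studies this emulates. Region 5 is the deviant site (D = 0.5
shifts on three variables incl. two dominant predictors, 0.3 on two more,
−5 outcome offset); the other regions carry |D| = 0.1 shifts on three
variables each and alternating ±2 outcome offsets, so the target itself is
mildly heterogeneous everywhere — matching the screening pattern such
registries show (most effects small, a few moderate, one region
distinct). The 27-country preset fixes site sizes on a deterministic
spread of 509–2933 (total 46 467), prevalences 0.06–0.25 — rare enough
that four mutually exclusive balanced test subsets always exist — small
fixed shifts everywhere and one strongly shifted country. Profile
parameters are fixed constants; the seed controls only sampling, so a
seed fully determines every table.

## Problem sizes and determinism

Replicate-study drivers (`fedsurvey.studies`) fix the reference
configurations: regression forests 100 trees, leaves ≥ 5; DP/attribution
forests 100 trees, depth ≤ 8, leaves ≥ 25 (depth-limited trees keep exact
tree-Shapley computation fast and DP noise per leaf bounded);
classification forests 54 depth-12 trees with √m feature subsampling.
Significance tallies use 20 replicate studies; fidelity, subsampling and
attribution checks use 10; null calibrations use 2000 simulated studies.
All randomness flows through integer seeds via `numpy` SeedSequence
spawning, so every table, fold plan, share mask, DP draw and forest is
reproducible from a single seed.

## What passing tests show — and what they do not

The exactness results (OLS federation, secret-sharing round trips, local
accuracy of attributions) are properties of the algorithms and transfer to
real data as stated. The comparative results (federated beating the local
average, the widening gap under data scarcity, top-5 attribution
agreement) are demonstrated on the synthetic presets; they show that the
pipeline reproduces the qualitative behavior expected under moderate,
known site heterogeneity, not that any particular real registry would
yield the same effect sizes. Real survey data add correlated ordinal
items, missingness (the presets are complete-case by construction),
informative site sizes and unmodelled confounding; none of these are
emulated here.
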