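# Methods

`mcishapley` re-implements, as a tested library, a subject-valuation
workflow for predicting conversion from mild cognitive impairment (MCI) to
Alzheimer's disease (AD) from tabular volumetric-MRI, demographic and
cognitive-score data. This note documents the models, the choices that were
genuinely open, and what the synthetic experiments do and do not show.

## The classification problem

Subjects with a baseline MCI diagnosis are labelled from their longitudinal
visit history: **sMCI** (stable) if every follow-up diagnosis is MCI,
**pMCI** (progressive) if they convert to a *stable* AD diagnosis (AD at
some visit and at every visit thereafter). Subjects are excluded, in fixed
flow order, when (1) the baseline diagnosis is not MCI, (2) no follow-up
diagnosis exists, (3) any diagnosis reverts (AD→MCI/CN or MCI→CN), or
(4) no baseline MRI is available. The order matters for the per-criterion
counts in the selection report, so it is fixed.

The model matrix holds 103 volumetric features (34 cortical parcellation
volumes per hemisphere, 34 subcortical/global segmentation volumes, eTIV),
three demographic features (age; gender as a female indicator; ApoE ε4
allele count as an ordinal 0/1/2) and three cognitive scores (MMSE,
LDELTOTAL, LIMMTOTAL). Regional volumes are divided by the subject's eTIV;
raw eTIV is kept as the 103rd volumetric feature, because eTIV/eTIV would
be a constant column.

Splitting is stratified within each diagnostic group at 65/15/20
(train/validation/test). Per class, `n_train = round(0.65·n_c)` and
`n_valid = round(0.15·n_c)` with half-away-from-zero rounding and the
remainder assigned to test — the one rounding rule that maps class sizes
(400, 319) to the totals 467/108/144. Centering and scaling parameters
(mean, population SD) are estimated on training rows only and re-applied
unchanged everywhere else.

MRI features are filtered by impurity-based random-forest importance
(50 trees) computed on the training rows; the mean importance over all 103
features is the retention threshold and ties at the threshold are kept
(only features *strictly below* the mean are dropped).

## Data valuation

The training set is treated as a cooperative game: the payoff `V(S)` of a
coalition `S` of training subjects is the validation accuracy of a base
classifier (logistic regression or random forest, fixed hyperparameters,
no tuning) fit on `S`. Three valuations are implemented:

- **Leave-one-out**: `Φ_i = V(D) − V(D∖{i})`. Greedy; does not satisfy
  the efficiency axiom.
- **Exact Shapley** (full subset enumeration, n ≤ 12):
  `Φ_i = (1/n) Σ_{S⊆D∖{i}} [V(S∪{i}) − V(S)] / C(n−1, |S|)`, which
  satisfies efficiency `Σ Φ_i = V(D) − V(∅)` to numerical precision and is
  the oracle for the Monte Carlo estimator.
- **TMC Shapley** (Truncated Monte Carlo): per random permutation,
  subjects are added one at a time and the change in validation accuracy
  is the added subject's marginal contribution; once the running score is
  within a truncation tolerance (default 0.01, absolute difference) of
  `V(D)`, the remaining marginals of that permutation are recorded as 0 —
  recorded, not skipped, so every permutation contributes one marginal per
  subject and the estimator remains an average in form. Values are the
  mean marginal over permutations. Four independently seeded runs are
  averaged by default.

Open points resolved here, as package choices:

- `V(∅)` is the accuracy of a majority-class predictor (majority taken
  over the full training pool; ties break to the lexicographically
  smallest class). Deterministic and reproducible.
- The truncation comparison uses the absolute difference `|V(D) − running|`.
- Convergence: every `save_every = 100` permutations, compute the running
  value estimates after each permutation, take the mean over subjects of
  the relative change against the current estimate, and stop when the
  maximum of this diagnostic over the trailing 100-permutation window
  falls below `err = 0.1`. A hard permutation budget caps the run either
  way, and the result records a convergence flag.
- Base-classifier refits within one permutation reuse a single model seed,
  so marginals reflect subject composition, not classifier randomness.
- Averaging values across equally budgeted runs equals averaging their
  marginals; the library averages values.

## Exclusion experiments

Training subjects are ranked by value and the `k` smallest-valued subjects
are removed (ties break by ascending subject id); a fresh classifier
ensemble — random forest (50 trees) or XGBoost (depth-6, eta 0.3,
subsample 0.6; 100 boosting rounds, the library default of the XGBoost
line used, since no round count is fixed by the workflow's parameter
table) — is trained once per repetition seed (10 by default) at each
gridpoint, yielding mean ± sd accuracy and F1 (positive class pMCI)
curves per evaluation set. The random-exclusion baseline redraws its
excluded set per gridpoint and repetition seed. Gridpoints whose training
subset degenerates to one class are recorded as missing rather than
failing the curve.

Cutoff rules: **zero-cutoff** removes every subject with a strictly
negative value (zero is retained); **max-valid** takes the argmax of mean
validation accuracy over the grid (ties toward fewer exclusions);
**max-test** does the same on the test set and is flagged optimistic —
a threshold tuned on the test set is not validated independently.

## Kernel SHAP

Feature attributions are estimated from scratch. For an instance `x`, a
model `f`, and a background set: binary coalitions `z ∈ {0,1}^M` select
which features take their value from `x`; the rest are imputed from each
background row and predictions are averaged. The attributions solve the
weighted least-squares problem with the Shapley kernel weight
`π(z) = (M−1) / (C(M,|z|)·|z|·(M−|z|))` and no complexity penalty. The
infinite-weight boundary coalitions are handled as hard constraints — the
base value is the mean background prediction and one attribution is
eliminated by the efficiency constraint — so local accuracy
`Φ₀ + Σ Φ_i = f(x)` holds exactly, not approximately.

When `2^M − 2 ≤ n_coalition_samples` (default budget 3000) all interior
coalitions are enumerated with their exact kernel weights and the result
coincides with the exact Shapley attribution of the imputation game
(verified against the full-enumeration `exact_shap` oracle and against the
closed form `Φ_i = w_i (x_i − x̄_i)` for linear models). Otherwise
coalitions are sampled with size probability proportional to the
aggregated kernel mass per size and uniform subsets within a size, which
makes the regression unweighted by importance sampling; the "auto"
regularization mode then applies an AIC-guided least-angle pruning step
before the constrained solve, and no pruning in the enumeration regime.

Classifiers are explained through their pMCI-probability output (identity
link). Summary displays order features by mean |Φ| (ties by name) and
min-max-normalize displayed MRI and cognitive values over the pooled
explained instances; force displays sort signed attributions by magnitude,
positive = pathogenic, negative = protective. The valuation-explanation
analysis fits, per diagnostic group, a 50-tree random-forest regressor of
the per-subject data values on the model features and explains it the same
way, with the group's own rows (subsampled to ≤ 100) as background.

## Synthetic cohort generator

The generator emulates the structure of the source cohorts so every stage
is testable without restricted-access data. Defaults reproduce the
published selection funnel (2250 subjects; 1219 non-MCI baseline, 124 no
follow-up, 101 reverters, 87 without usable baseline MRI; 719 selected:
400 sMCI / 319 pMCI) and the published class summaries: MMSE 27.8 ± 1.8
(sMCI) vs 27.0 ± 1.7 (pMCI); age 73.2 ± 7.5 vs 74.0 ± 7.1; ~40% female in
both groups; ApoE ε4 allele-count distributions (0.568, 0.340, 0.092) vs
(0.342, 0.495, 0.163). Exact category counts follow half-away-from-zero
rounding of the configured fractions, so planted exclusion counts are
recoverable by hand.

Choices where the sources are silent:

- **Volumes** are truncated-at-zero Gaussians around representative
  per-region means (e.g. hippocampus ≈ 4.2 mL, eTIV ≈ 1.5 L) with a 12%
  coefficient of variation. A single latent "atrophy severity" factor per
  subject (loading 0.5) induces inter-regional correlation — enough to make
  feature selection and SHAP non-degenerate; it is a stand-in, not an
  inference about real covariance structure.
- **Effect directions**: pMCI means are shifted by per-region standardized
  effect sizes — 0.5 SD for the medial-temporal AD signature (hippocampus,
  amygdala, entorhinal, middle/inferior temporal, fusiform,
  parahippocampal), −0.35 SD for ventricles (enlarged in pMCI), 0.15 SD
  elsewhere.
- **Cognitive scores** are integer-rounded and clipped to instrument
  ranges (MMSE 0–30, logical-memory scores 0–25). LDELTOTAL and LIMMTOTAL
  class means are not published in the cohort table; ADNI-like values
  (8.0 ± 3.5 vs 4.5 ± 3.0 and 11.0 ± 4.0 vs 8.0 ± 3.5) were chosen once.
- **Label noise** flips exactly `round(fraction·n)` uniformly chosen
  labels and records their ids, providing ground truth for recovery
  experiments.

What passing synthetic tests show — and what they do not: the generator
has Gaussian class-conditional structure, a one-factor covariance, and no
site effects, scanner effects, missingness, or label ambiguity beyond the
planted flips. Recovery of planted noise therefore demonstrates that the
valuation machinery ranks genuinely harmful training points low under
clean conditions; it does not certify comparable effect sizes on real
multi-site cohorts.

## Problem sizes used in the checks

The recovery experiments use 200 training, 100 validation and 100 test
subjects with 20% planted label noise, a logistic-regression payoff, and
the 4-iteration TMC averaging at 150 permutations per iteration; five
experiment seeds are evaluated and statistical claims are made over seeds,
not per run. The exclusion comparison trains 10-seed random-forest
ensembles at the planted-noise exclusion count. Oracle agreement uses an
n = 8 deterministic concave payoff (TMC at 2000 permutations vs exact
enumeration) and M = 8 tree models for Kernel SHAP vs exact enumeration.

## Known limitations

- Exact enumeration is capped at n (or M) = 12 by design; beyond that the
  Monte Carlo paths are the only route, with Monte Carlo error.
- The TMC convergence diagnostic is scale-sensitive for subjects with
  near-zero values (relative change); the permutation budget is the
  effective stop in small experiments.
- Accuracy payoffs are quantized at 1/|validation set|, so truncation
  tolerances below that granularity behave like zero.
- The generator's latent-factor covariance is deliberately simple; do not
  interpret synthetic feature-importance patterns as neuroanatomy.
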