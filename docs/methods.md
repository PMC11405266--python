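# Methods

## The model

The clock is a gradient-boosted tree regressor (LightGBM) mapping a
complete, normalized samples-by-proteins matrix to chronological age.
Boosting is capped at 5,000 trees with early stopping after 20 rounds
without improvement of holdout R²; R² is supplied as a custom
evaluation metric so the stopping criterion is the quantity being
reported. Training follows the standard protocol for this family of
analyses: a 70:30 train/test split for model development, fivefold
cross-validation for tuning and for the cohort-wide prediction, and a
single sex-combined model.

The quantity of interest is not the prediction itself but the **age
gap** `gap = protage − age`. For the gap to be interpretable for every
participant, `protage` is computed out-of-fold: the cohort is split
into k = 5 folds and each fold is predicted by a model trained on the
other four (the held-out fold doubles as that model's early-stopping
set — the fold's predictions are still made by a model that never used
its labels for gradient fitting; only the stopping round is informed by
them, a compromise we accept to avoid carving a third partition out of
each training fold). Gap summaries report decile means and the
top/bottom 5% band means, whose difference is the headline contrast of
accelerated versus decelerated agers.

### Hyperparameter search

Tuning is a seeded random search (200 candidate draws by default)
maximising mean fivefold CV R². The space: learning rate
log-uniform [0.01, 0.2]; leaves 8–128; depth 3–12; row subsampling
[0.5, 1]; feature fraction [0.2, 1]; L1/L2 regularisation log-uniform
[1e-8, 10]; minimum leaf size 5–100. Defaults (learning rate 0.05,
31 leaves, feature fraction 0.8) are deliberately conservative and are
used wherever tuning is skipped. All boosters run single-threaded
deterministic (`deterministic=true, force_row_wise=true,
num_threads=1`), trading speed for bitwise reproducibility.

## Feature selection

**Shadow-feature (Boruta) selection.** Within an iteration, each of
`trials` fits appends one freshly permuted shadow copy of every
surviving feature, refits the clock on the augmented matrix, and
computes each column's mean absolute Shapley attribution over the
training samples. A real feature fails if its trial-averaged importance
does not exceed the trial-averaged threshold-quantile of shadow
importances — the shadow *maximum* at the default 100% threshold.
Failing features are dropped and the iteration repeats until none fail.
Averaging over trials before comparing (rather than counting per-trial
hits) keeps the decision rule monotone in importance and gives tight
false-positive control: on pure noise the expected selection is ≤1
feature, because beating the maximum of p shadow importances *on
average* requires consistently ranking at the top.

**SHAP-driven recursive elimination.** Starting from the selected
panel, each step fits k = 5 CV models, records mean CV Pearson r and
R², and removes the protein with the smallest mean-|SHAP| importance.
When folds disagree about the minimum, the protein ranked lowest in
the greatest number of folds is removed; residual ties break
lexicographically by protein id. Elimination proceeds to a terminal
five-protein panel, and the reduced clock is the smallest panel whose
CV metric retains 95% of the full panel's value. Tuned hyperparameters
are reused throughout the elimination (per-step re-tuning would
multiply the cost by the trial count without changing the ranking
logic).

## Shapley attributions

Per-sample attributions use the exact path-dependent TreeSHAP values
the booster itself computes (`pred_contrib`). Pairwise **interaction**
values, which the booster does not expose, are computed in
`protclock.treeshap` by the conditioned weighted-path recursion on the
dumped tree structure: for features i ≠ j,
`Φ[i,j] = (φ_j | i forced in − φ_j | i held out) / 2`, with the
diagonal absorbing main effects so each signed row sums to the
feature's attribution and the matrix total reconstructs
`f(x) − E[f]`. Conditional expectations are path-dependent (absent
features follow both branches weighted by training cover), matching
the value function of the unconditioned attributions. The test suite
checks both routes against a brute-force subset-enumeration Shapley
oracle to 1e-8 on small models, and checks additivity, symmetry and
row-sum reconstruction on every fitted model it touches. The recursion
is numba-compiled with a pure-Python fallback.

## Epidemiological analyses

Association scans regress each phenotype on the gap (linear for
continuous, logistic for binary) adjusted for age, sex, deprivation
score, a categorical assessment-centre analogue, activity group and
smoking status; Benjamini–Hochberg FDR is applied per scan family.
Survival analyses exclude prevalent cases per endpoint, then fit Cox
proportional hazards models (lifelines, Efron ties) in three covariate
tiers — (1) age + sex, (2) + deprivation/centre/activity/smoking,
(3) + BMI and hypertension — reporting the hazard ratio per gap-year
with BH-FDR across endpoints within a tier. Endpoints with fewer than
10 events are flagged low-power rather than suppressed. Kaplan–Meier
cumulative incidence (1 − S) is computed for gap deciles ("median"
means the 5th decile, the 40–50th percentile band; deciles are formed
on the post-exclusion analysis sample). By the plotting convention of
this analysis family the curve is indexed by age at recruitment — the
value at age a is the cumulative event fraction over follow-up among
participants recruited at or before a; a follow-up-time axis is
available as an option. Fold risk compounds a per-year hazard ratio
over a gap contrast as `hr ** years`. Multimorbidity trends report the
mean gap by lifetime diagnosis count (0, 1, 2, 3, 4+), optionally per
age stratum, with t-interval CIs.

## Interaction networks

The mean absolute interaction matrix over an evaluation sample defines
a weighted protein network: off-diagonal entries at or above a
threshold become edges. Because the published absolute threshold
(0.0083) is dataset-specific, the default mode instead auto-selects
the smallest threshold whose network does not exceed a target node
count (e.g. the size of a reference subnetwork); any absolute
threshold can be passed explicitly. Reference coexpression edge lists
are filtered at confidence strictly above 0.7 and then pruned
*iteratively* to nodes with at least two connections (one-pass pruning
can leave new degree-1 nodes behind; the fixed point is
order-independent). Networks are compared by node and edge Jaccard
overlap.

## The synthetic cohort generator

The generator emulates what the analysis needs from a biobank-scale
proteomics cohort, not the assay itself. Per sample, age is uniform on
39–71 years and a latent aging deviation δ ~ N(0, sd²) (default sd
2 years) defines a biological age `age + δ`. Per protein,
`x = μ + β·(age + δ) + ε` with baseline μ ~ N(0, 1), residual
ε ~ N(0, noise_sd²) (default 0.3 NPX), and slope β either drawn
N(0, slope_scale²) (default 0.02 NPX/yr) or planted at ±slope_scale
exactly (`slope_dist="fixed"`). A configurable fraction of aging
proteins receives a centred quadratic age term. Survival endpoints
draw Weibull (default exponential) event times with hazard
`λ0·exp(γδ)`, administrative censoring at the follow-up horizon, and
prevalent flags assigned independently of δ by default (an optional
δ-dependent mode exists; independence keeps incidence analyses
unconfounded). Phenotypes load linearly on δ (binary ones through a
logistic link at a 20% base rate). Missingness is MCAR or
below-detection (masking each protein's lowest values, as LOD
censoring would). Covariates: sex Bernoulli(0.5), deprivation N(0,1),
BMI N(27, 4.8²), hypertension Bernoulli(0.3), and fixed multinomials
for centre (5 levels), activity and smoking (3 levels each).

The **high-SNR benchmark** (`high_snr_config`) is n = 3,000 samples,
500 proteins of which 50 are aging-related with fixed ±0.04 NPX/yr
slopes against 0.2 NPX residual noise, δ sd 2 years. The fixed
magnitude makes all fifty genuinely signal proteins (a Gaussian draw
would leave several with negligible slopes), and the implied
per-protein age correlations (~0.6–0.8) match the strongest plasma
agers reported in this literature. Under these conditions the clock
reaches out-of-fold r ≈ 0.97 and the gap recovers δ at r ≈ 0.82.

What the generator deliberately does *not* emulate: plate/batch
effects, bridging normalization, non-Gaussian NPX distributions,
longitudinal repeat visits, genotypes, and realistic disease-specific
covariate confounding. Passing tests therefore demonstrate that the
*procedures* are correct and well-calibrated under their stated
assumptions, not that real-cohort effect sizes would be reproduced.

## Numerical and design choices

- Seeds: one run seed fans out to per-stage seeds as
  `(seed·1000003 + crc32(stage)) mod 2³¹`; the survival simulator uses
  a keyed generator stream so an identical integer seed never yields
  draws correlated with the cohort generator's stream.
- Strict thresholds follow their wording: "over 10%" missingness
  excludes at > 0.10 exactly; reference confidence keeps > 0.7 exactly.
- Constant proteins normalize to 0 with a logged warning; zero-variance
  exposures and single-class binary phenotypes are flagged or skipped,
  not errors.
- Normalization fits on the training subset by default and applies
  stored parameters elsewhere; `paper_mode` fits on the full cohort
  per-cohort for faithful replication of the original protocol (which
  did not document the fit/split order).
- Chained imputation is a median-initialised chained-equations loop
  with one ridge regression per incomplete protein per round (max 5
  rounds, predictors restricted to proteins with ≤30% missingness);
  observed cells are bit-identical after imputation.
- Problem sizes in the test suite (e.g. Boruta at 6 trials, RFE
  cohorts of 600, 100-run null coverage at n = 2,000) are chosen so the
  statistical claims are testable with comfortable margins on a single
  CPU; the operations themselves scale to cohort sizes in the tens of
  thousands.

## Known limitations

- Random search replaces Bayesian (TPE) tuning; at equal trial counts
  it explores the space less efficiently, though the documented space
  is small enough for 200 trials to cover well.
- Path-dependent Shapley values inherit the known biases of cover
  weighting when features are strongly correlated.
- The Boruta trial-averaged decision rule is one reading of a
  procedure whose published description mixes one-shot and iterative
  semantics; the iterative reading implemented here is the one its
  stopping sentence describes.
- The recruitment-age axis for cumulative incidence is a plotting
  convention, not a left-truncated survival model; absolute incidence
  values on that axis mix follow-up windows across recruitment ages.
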