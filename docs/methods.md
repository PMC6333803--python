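# Methods

This note documents the models, conventions and numerical choices
behind `hemoclock`, and what its synthetic-cohort tests do and do not
establish.

## The synthetic cohort

The generator stands in for a private administrative dataset; nothing
about real marker distributions is reproducible, so the generator is a
*stated world* built to make every downstream procedure exercisable and
its planted parameters recoverable.

**Ages** are a deterministic evenly spaced grid over `age_range`
(default [18, 92]), rounded to integer years and shuffled with the
seed. This makes the cohort median exactly the range midpoint (55) by
construction, so cohort-level checks are deterministic rather than
distributional.

**Sex and smoking** are quota assignments, not Bernoulli draws: sex
alternates within each 10-year age group (counts differ by at most 1),
and the smoker count equals `round(smoker_fraction × n)` exactly,
allocated across (age group × sex) cells by largest remainder. Balance
within age groups therefore holds exactly, mirroring a cohort matched
on age and sex.

**Markers.** Each marker is
`mean_by_sex[sex] + slope · (B − 55) + offset · smoking + N(0, sd)`,
with latent biological age `B = f_sex · age` for smokers below the
plateau age and `B = age` otherwise (a `taper` mode interpolates the
factor to 1 over a configurable window past the plateau instead of the
default hard cutoff). A `saturating` response shape
(`slope · s · tanh((B − 55)/s)`, `s` = half the age range) exists for
robustness tests. Markers are conditionally independent given
(B, sex, smoking) — real inter-marker correlation structure is *not*
emulated, and neither are longitudinal records or survivorship.

**Signal-to-noise is deliberately generous.** The default panel gives
15 markers 0.06 SD/year of biological age and 10 markers 0.03 SD/year;
jointly that implies an ideal-observer age precision of ~4 years
(R² ≈ 0.95), far above what real clinical chemistry supports. This is
intentional: the acceptance-style recovery checks require the clock to
read B accurately enough that the mean log2 aging ratio of accelerated
smokers lands within 0.1 of log2(f_sex), which a realistically weak
panel (R² ≈ 0.56) cannot do because shrinkage toward the mean age
biases the ratio downward. A green recovery test therefore establishes
that the *pipeline* recovers planted structure, not that real blood
panels carry this much signal.

**Direct smoking offsets** (HDL down; hemoglobin, RDW, MCV up; default
0.5 SD, configurable via `default_panel(smoking_offset_sd=...)`) give
the smoking classifier signal beyond the age acceleration. These four
markers have zero age slope in the default panel — their real age
trends are weak, and keeping them age-flat prevents the offsets from
leaking a spurious age-acceleration signal into the nonsmoker-trained
clock for smokers above the plateau.

**Missingness** is quota-exact and completely at random per marker
(`round(missing_rate × n)` cells). Eight endocrine/iron-panel markers
carry 40–60% missingness and act as reconstruction targets; most others
are near-complete so that complete-case analyses retain subjects.

## Arbitrage feature selection

320 random-forest age regressors (80 trees each; `min_samples_leaf=2`,
`max_features="sqrt"`, other hyperparameters default) are trained on
distinct feature spaces. How the original feature spaces were built is
not specified anywhere, so the package constructs them as (a) the
cohort's co-missingness blocks — the distinct observed-marker patterns,
which are the maximal marker sets sharing fully observed subjects —
plus (b) seeded random subsets at sizes 5..K (1..K for K ≤ 5), keeping
only spaces with at least `min_eligible` (default 50) complete cases,
until the requested count of distinct spaces exists. Requests exceeding
the number of distinct subsets fail with the attainable maximum.

Per model, complete cases are split 80/20 (seeded per space index),
MAE_i is the held-out mean absolute error, and q_i is permutation
importance on the held-out split — the operational reading of "mean
decrease accuracy" that is estimator-agnostic and uses no training-set
impurity. The permutation scorer stacks all (feature × repeat) permuted
copies of the test block into a single ensemble predict call; sklearn's
`permutation_importance` computes the same estimand (cross-checked in
tests) but is an order of magnitude slower at these test-set sizes.

`FI = Σ q_i / MAE_i` over the models containing the marker. A model
with MAE_i = 0 is an error (the weight is undefined), as is a record
missing an importance for one of its markers. Ties anywhere break by
descending FI then ascending marker name, so rankings are deterministic
under permutation of the input.

**Feature-set selection.** Markers are added greedily in FI order and
the complete-case count of each prefix recorded. A prefix size is a
*knee* when adding the next marker loses more than `drop_fraction`
(default 10%) of the eligible subjects. The `n_sets` knees with the
largest eligible counts are returned (topped up by the sizes maximizing
eligible_n × size when knees are scarce — on a complete cohort this
degenerates to the maximal set and its prefixes). `max_features="sqrt"`
matters here: with all-features splits, weak markers receive
essentially zero permutation importance next to dominant ones and
their ranking is noise; square-root feature sampling forces them into
trees and preserves the slope ordering the knee structure relies on.

## Reconstruction

A target marker is regressed (OLS) on the feature space's fully
observed markers plus age and sex, over the subjects where it was
measured, then predicted deterministically into its missing cells — no
stochastic imputation, matching a single-prediction reconstruction.
Targets qualify when the fraction of the space's subjects available to
fit lies in [0.30, 0.60]; because the band is evaluated *per feature
space*, structured missingness can qualify a marker for a larger space
but not a smaller one, which is how the packaged nested fixture expands
14/15/18-marker spaces to 18/20/23. Fill order is ascending
missingness so earlier reconstructions can serve later ones; observed
values are never overwritten, every cell carries an
observed-vs-reconstructed provenance flag, and unfillable cells (a
missing predictor) are left missing and counted. Rank-deficient
designs fail with the collinear predictors named (QR with pivoting).

## Age and smoking models

The estimator contract is deliberately open — anything minimizing mean
absolute error (binary cross-entropy for the classifier) at desk scale
satisfies it. Three kinds ship:

- `mlp` (default): a small fully connected network, two hidden layers,
  width selected from {16, 32, 64} by k-fold cross-validation (default
  5 folds) on negative MAE / F1, ReLU, Adam, early stopping, inputs
  standardized. scikit-learn's networks have no dropout layer; the
  35%-dropout regularization of the original deep models is replaced
  by L2 (`alpha=1e-3`) plus early stopping.
- `gbt`: histogram gradient boosting with an absolute-error loss — the
  only estimator here whose loss *is* the MAE; fast and deterministic,
  used by the recovery tests.
- `linear`: OLS / logistic regression, for contract tests and oracles.

Training on nonsmokers enforces two guards: the train set must contain
no smokers, and smoking status is refused as a feature (it would be
constant, and worse, would contaminate the biological-age readout);
both are lifted in the `all_with_smoking_feature` mode used for the
augmented models. The smoking classifier always refuses the label as a
feature. Train/test splitting is stratified by age decade (singleton
decades merge into the nearest populated one) to stabilize tail-age
error estimates; normalization statistics come from the train set only.

Metrics: Pearson r, R² (1 − SSE/SST on held-out data; negative for bad
models), MAE, and ε-accuracy with a **closed** interval — a prediction
exactly ε years off counts as correct (default ε = 10). Zero-variance
targets make r and R² undefined (`None`), not numbers. Classification
reports carry the confusion counts alongside accuracy, precision,
recall and F1 (smoker = positive class); zero-denominator metrics are
`None`. Age-binned confusion matrices use integer bins <31, 31–40,
41–50, 51–60, 61–70, >70; empty bins are reported with zero counts.

## Aging-ratio analysis

The log2 aging ratio is per-sample (not a ratio of group means).
Nonpositive *predicted* ages — possible from an unconstrained
regressor — are excluded and counted; nonpositive chronological ages
are an input error. Group summaries report mean ± SD (matching
mean-and-error-bar presentation) per (age group × sex × smoking) cell,
with a two-tailed Mann–Whitney p per (age group × sex) pair: exact for
tie-free cells of ≤ 50, asymptotic (tie-corrected) otherwise;
significance at p < 0.05. Empty cells appear with n = 0 and undefined
statistics.

Cardiovascular risk quadrants are the full 2×2 of
(total/HDL cholesterol ratio > 4) × (fasting glucose > 5 mmol/L), with
complements taking ≤; rows with HDL ≤ 0 or missing inputs are excluded
and counted. The biweight midcorrelation uses median centering and
Tukey biweights at 9 raw MADs (zero weight at or beyond the cutoff);
zero MAD is an error. It matches an independently coded textbook
implementation and pingouin's `bicor` to 1e-10 in tests.

## Importance analysis

Permutation importance is signed so larger = more important: MAE
increase for regression, F1/accuracy decrease for classification;
default 10 repeats, mean ± SD, computed on held-out data (the standard
choice; whether the original ranking used train or test data is
unknown). Partial dependence forces one feature across a grid ({0, 1}
for binary features) with all other features at observed rows and
averages the model output.

**A known sign disagreement.** On real cohorts, partial dependence of
predicted age on smoking status was reported positive. Under this
package's generative model the conditional truth has the opposite
sign: markers encode biological age B, smokers below the plateau have
B = f·age, so *given the markers* a smoker is chronologically younger
and any consistent regressor learns PD(smoking=1) < PD(smoking=0). The
corresponding acceptance check is implemented as stated and fails by
design of the world; the smoking feature's permutation importance is
nevertheless strongly positive, because the conditional dependence is
real. No generator parameter was adjusted to chase the reported sign.

## Determinism and scale

Every stochastic step takes a seed (per-space seeds derive as
`seed·100003 + index mod 2³¹`); identical configuration reproduces
cohort CSVs byte-for-byte and pipeline artifacts bit-for-bit. The test
suite runs the full 320-model arbitrage stage twice (default cohort at
n = 500 and the tiered fixture at n = 1500, ~40 s each on one CPU);
the planted-recovery checks use the `gbt` estimator at n = 10,000 and
n = 5,000. The fixture-recovery test raises `min_eligible` to 150:
feature spaces with ~50 eligible subjects have ~10-row test splits
whose permutation-importance noise can swamp the weakest planted tier.

## Limitations

- Marker independence given (B, sex, smoking): reconstruction quality
  on the default panel is modest by construction (targets depend on
  age/sex only); exact-recovery tests plant explicit linear
  dependences instead.
- No probability calibration, no multiple-imputation uncertainty, no
  causal reading of the smoking effect.
- The "autoregressive" description of reconstruction is treated as the
  same OLS procedure as the linear-regression description; the two are
  not distinguished here.
- Plotting is not bundled; all outputs are TSV/CSV/JSON tables that
  plot directly with any standard tool.
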