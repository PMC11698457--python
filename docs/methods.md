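# Methods

This note documents the models, the numerical choices, and what the
synthetic studies do and do not establish.

## Data model and preprocessing

The pipeline consumes a sample × feature matrix of nonnegative LC-MS peak
responses (0 = not detected) with sample metadata (percent ethanol of the
extraction solvent, replicate number) and per-sample IC₅₀ values (ppm) for
the AGI and DPPH assays.  Regression targets are the reciprocals 1/IC₅₀, so
larger means more active.  Features are unit-variance (UV) autoscaled:
centred and divided by the n−1 sample standard deviation.  Zero-variance
features are dropped with a warning rather than erroring, so degenerate
configurations still run; missing values are rejected outright, because gap
filling belongs to the upstream peak-processing stage.  No log transform is
applied before scaling by default — the raw response scale is what the
loading and correlation analyses are defined on.  Feature order is file
order and is never re-sorted; every selection stage identifies features by
`var_id`, and consensus voting depends on stable identity, not position.

The discriminant-analysis class split is fixed by design: the 100 %-ethanol
extracts form the active class, everything else non-active.  The DA
response is encoded as two complementary indicator columns, UV-scaled.
That pair has rank 1; the orthogonal-projection variants therefore receive
one predictive component for it, not two (asking NIPALS for a second
component of a rank-1 response only fits noise).

## Branch A: projection models

PCA and PLS use NIPALS with deterministic initialisation (the
largest-variance column) and deflation `X ← X − t pᵀ`, `Y ← Y − t cᵀ`.
OPLS removes components orthogonal to the response before a final PLS: per
round, one NIPALS component is extracted, its loading is projected off the
orthonormal basis of span(XᵀY), and the resulting orthogonal score/loading
pair is deflated from X.  For a univariate response with one predictive
component this reproduces the classic identity fitted-Y(OPLS 1+a) =
fitted-Y(PLS a+1), which the tests assert to 1e−6.

Q² is cumulative 1 − PRESS/SS over 7 interleaved cross-validation folds
(the fold count is configurable; interleaved assignment is the conventional
default for small designed studies).  Folds refit the projection on the
training rows of the already-scaled matrices; scaling is treated as a fixed
preprocessing step, not re-estimated per fold.

Component counts are chosen by "add a component while Q² improves by more
than 0.05", capped at 5 predictive (plus up to 5 orthogonal for OPLS).  The
entry threshold is deliberately conservative: at n = 30 a marginal extra
component roughly doubles the R²Y a *shuffled* response can reach, which
would defeat the permutation check below while adding almost no genuine
predictive skill.

### Validity gate

1. **Overfit gap** R²Y − Q² ≤ 0.3.
2. **Response permutation** (20 rounds): whole response rows are shuffled
   (multi-target responses stay paired), the model is refit at the same
   size, and R²Y/Q² are regressed on the absolute correlation of the
   shuffled response with the original; the unpermuted point anchors the
   line at correlation 1 (configurable off).  Intercepts at correlation 0
   must satisfy R² ≤ 0.4 and Q² ≤ 0.05.
3. **CV-ANOVA** per response column:
   F = ((SS − PRESS)/A) / (PRESS/(N−1−A)) with A the total number of
   components, upper-tail p ≤ 0.05; a model no better than the response
   mean gets F = 0, p = 1.

A known property of this F-formulation, confirmed here by simulation, is
conservatism under the null: a component trained on an information-free
response usually cross-validates worse than the mean (PRESS ≥ SS), so the
null p-value distribution piles up near 1 rather than being uniform.  Its
rejection rate at the 0.05 level is nonetheless approximately 0.05, and its
power on planted signal is essentially 1, which is what the gate needs.

### Feature selection

For each valid model the first predictive component is oriented by the sign
of corr(t₁, target) — so "most activity-aligned" is well defined whichever
way the component happens to point — and features are ranked by oriented
loading, filtered to VIP > 1, truncated to 25.  Ranking uses the first
component only; a multi-component weighted ranking exists behind a switch
but is off by default, since the first component carries the activity
separation by construction.  Ties keep file order.  The statistical vote is
strict (> 50 % of valid-model lists), matching how the branch rule is
worded; the ML vote below is non-strict (≥ 50 %).

## Branch B: machine learning

Fixed study settings: decision tree — binary splits, min 2 samples per
leaf, no split below 5 samples, and a 95 % "purity" stop, which for
regression is read as: stop predicting deeper once node variance falls to
≤ 5 % of the root variance (implemented as an early-stopping prediction
walk over the fitted tree — equivalent to not splitting such nodes);
random forest — 100 trees, min split 2; gradient boosting — 100 trees,
depth 3, learning rate 0.05; AdaBoost — 100 stumps, linear loss, learning
rate 0.01.  A note on AdaBoost: "SAMME.R" is a classification weighting
scheme; for a continuous target the matching algorithm is AdaBoost.R2 with
linear loss, which is what is used.  An ANN is deliberately absent from the
default suite (it contributes no importance list downstream); the suite is
extensible via `MLConfig.overrides`.

The 50/50 split is stratified by solvent class.  Bootstrap augmentation
(stratified, with replacement, to 50 rows) defaults to
*split-then-augment*: each side of the split is augmented separately, so no
test row shares provenance with a training row.  The leakier
*augment-then-split* order is available to mirror pooled-resampling
practice, with provenance recorded either way.

Permutation importance is the mean RMSE increase over 100 shuffles of one
feature, evaluated on the data the model was trained on (the evaluation set
is configurable); shuffles are batched into single prediction calls, which
is numerically identical to scoring them one at a time.  A feature no tree
ever splits on scores exactly 0.

Shapley values use an exact interventional algorithm: for each tree leaf
and each (foreground, background) sample pair, the path constraints
classify features as irrelevant, required-from-x (a of them) or
required-from-z (b of them), and the leaf value contributes the closed-form
weights +v·(a−1)!b!/(a+b)! and −v·a!(b−1)!/(a+b)! respectively.  The
background set defaults to the evaluation matrix itself.  Local accuracy
(Σⱼφᵢⱼ + base = prediction) holds to machine precision and the
implementation is pinned to brute-force coalition enumeration in the tests.
The reported SHAP score is the mean absolute Shapley value per feature, so
positive and negative influence both register.

Each of the five lists (permutation and SHAP importances for the forest
with and without bootstrap, plus the top-25 correlation ranking) is capped
at 25 and sign-screened against the raw feature–target correlations before
the ≥ 50 % vote.  The screen is what removes influential *suppressor*
features — the importance analyses find them, the correlation sign rules
them out as bioactive candidates.

## Consensus and post-analysis

The final features are the intersection of the branch selections, ordered
by variable id.  The m/z merge defaults to exact equality after rounding to
3 decimals (the precision feature tables print); a ppm mode serves raw
instrument values.  Compound grouping is average-linkage hierarchical
clustering at distance 1 − r cut at 0.5 — a reproducible stand-in for
reading a correlation heat map by eye, and the cut is configurable because
no quantitative threshold is canonical.  The activity cross-correlation is
the plain 4×4 Pearson matrix over {1/IC₅₀, IC₅₀} × {AGI, DPPH}.

## Synthetic studies

The generator draws log-normal responses
`log R = b_j + trend_j·e + global factors + block factor + replicate noise`
over 5 solvent classes × 6 replicates and 80 features.  Defaults, chosen
once to emulate the study design:

| parameter | default | meaning |
|---|---|---|
| `effect_size` | 3.0 | ethanol trend of planted features (log units over the gradient) |
| `background_trend_sd` | 0.35 | random solvent trends of all other features |
| `n_global_factors`, `global_loading_sd` | 3, 0.3 | shared sample-level variation (matrix/extraction state) |
| `block_factor_sd` | 0.5 | within-block latent factor (3 blocks; two inside the actives, one mixed) |
| `replicate_noise_sd` | 0.03 | technical repeatability (~3 % CV) |
| `noise_sd` | 5.0 | activity noise on the latent 1/IC₅₀ scale |

Activity is the weighted sum of standardized planted-active responses minus
the planted-negative responses plus noise, generated on the 1/IC₅₀ scale,
affinely placed in [≈1, 3] so IC₅₀ stays positive and nearly linear in
activity, then inverted; the DPPH activity shares the same drivers with
independent noise.  Two planted actives share one m/z value, so the
compound merge is exercised with known truth.

Three structural choices matter and are worth stating:

* **Low effective rank.**  Background features carry random solvent trends
  and shared global factors, with small replicate noise.  Real
  extract-gradient peak tables are like this — most compounds co-vary with
  solvent polarity and sample state.  With 80 near-independent columns
  instead, a one-component PLS fits *any* shuffled response at R² ≈ 0.6 and
  the permutation intercept criterion could never behave as it does on real
  data.
* **Within-class activity signal.**  The block factors give compound
  families replicate-to-replicate variation that the activity follows.
  Without it, activity would be a pure function of the solvent gradient and
  nothing could distinguish planted actives from features that merely track
  the solvent.
* **Calibrated effect size.**  With the defaults, single planted features
  correlate with 1/IC₅₀ AGI at ≈ 0.72 on average (range ≈ 0.35–0.9),
  the validity gate passes ≈ 96 % of supervised models on planted signal
  and ≈ 1–3 % under a global null, and the end-to-end consensus recovers
  ≈ 90 % of planted actives with ≈ 15–20 % contamination over 20 seeds.

What passing these synthetic studies does **not** show: robustness to
nonlinear feature–activity relationships, to missingness/gap-filling
artefacts, to retention-time misalignment or adduct/isotope redundancy
beyond a single duplicated m/z, or to activity driven by compounds below
detection.  The generator plants a linear activity model; the ML branch's
advantage over the projection branch on real data (nonlinearity) is only
weakly probed.

## Numerical conventions and edge cases

* Sample statistics use the n−1 denominator throughout.
* NIPALS initialises deterministically and raises, naming the achievable
  rank, when more components are requested than the matrix supports.
* Requested problem sizes in the test-suite simulations (20 seeds for
  recovery, 50–200 trials for calibrations) were chosen so the whole suite
  runs in a few minutes on one CPU while estimating each rate to a few
  percent.
* Voting with zero source lists is an error; a gate that validates zero
  models yields an empty branch and an empty final set, which the pipeline
  reports as a warning, not a failure.
* All stochastic stages take explicit seeds derived from one pipeline seed
  via named seed streams; deterministic outputs are bit-reproducible from
  the run manifest.

## Known limitations

* The per-sample IC₅₀ table of the bundled case study is not available in
  data form, so its activity cross-correlation matrix cannot be recomputed
  here — only the branch lists and annotations are shipped.
* CV-ANOVA's null p-values are conservative (see above); the gate treats it
  as a screen, not a calibrated significance statement.
* The exact component counts and cross-validation layout of the original
  SIMCA analyses are unreported; the suite reproduces the procedure, not
  table-for-table numbers, which would require the undeposited raw matrix.
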