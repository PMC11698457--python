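# metabovote

Consensus prediction of bioactive metabolites from an untargeted LC-MS
feature table and bioassay activities.

## The problem

A bioassay-guided metabolomics screen produces a sample × feature table of
LC-MS peak responses (each *m/z* feature proxies one, usually unidentified,
metabolite) together with per-sample IC₅₀ values from activity assays —
here α-glucosidase inhibition (AGI, the antidiabetic target) and the DPPH
antioxidant assay.  The question is which of the detected features are the
bioactive compounds.  A single feature-selection method answers this
unreliably at n ≈ 30 samples, so `metabovote` implements a two-branch
consensus:

**Branch A — validity-gated projection models.**  A suite of 25 latent-
variable models (PCA; PLS and OPLS on 1/IC₅₀ or IC₅₀ of either assay,
single- or two-target; PLS-DA/OPLS-DA on the active/non-active class split)
is fitted by NIPALS to the unit-variance-scaled table.  Each supervised
model must pass three validity criteria before it may nominate features:

* overfit gap R²Y − Q² ≤ 0.3, with Q² = 1 − PRESS/SS the cross-validated
  predictive fraction (7 interleaved folds);
* a 20-round response-permutation test: regressing permuted R²Y and Q²
  on |corr(y_perm, y)| must give intercepts ≤ 0.4 and ≤ 0.05;
* CV-ANOVA p ≤ 0.05 per response (F-test of cross-validated residuals
  against the mean-only model).

Each valid model ranks features by their activity-aligned loading on the
first predictive component, keeps those with VIP > 1
(VIP²ⱼ = p·Σₐ SSYₐ (wₐⱼ/‖wₐ‖)² / Σₐ SSYₐ, so mean VIP² = 1), and nominates
the top 25.  Features appearing in **more than 50 %** of the valid-model
lists form the statistical selection.

**Branch B — tree-ensemble importances.**  Five regressors (linear
baseline, purity-stopped binary tree, 100-tree random forest, gradient
boosting, AdaBoost stumps) predict 1/IC₅₀ AGI on a random 50/50 split, with
and without stratified bootstrap augmentation to 50 samples.  The random
forest — consistently the best on test RMSE — is analysed by (i)
permutation importance, the mean RMSE increase over 100 shuffles per
feature, and (ii) SHAP scores, the mean |Shapley value| per feature from an
**exact** interventional tree-Shapley algorithm (closed-form coalition
weights per leaf, verified against brute-force enumeration).  These four
lists plus the top-25 correlation ranking are sign-screened (features whose
raw correlation with 1/IC₅₀ AGI is ≤ 0 are removed — influential
suppressors are not bioactive candidates) and voted at **≥ 50 %**.

The final prediction is the intersection of the two branch selections;
features whose m/z agree (3-decimal match, or ppm tolerance) are merged
into one predicted compound.  Post-analysis reports the correlation matrix
of the top candidates with average-linkage grouping, and the 4×4
cross-correlation of the activity variables.

A synthetic-study generator (`metabovote.synthetic`) emulates the study
design — 5 ethanol/water solvent classes × 6 replicates, 80 features,
planted positive and negative activity drivers, correlated feature blocks —
so every stage is testable against a known ground truth.

## Worked example

The bundled case study ships the two published branch consensus lists from
an *Artabotrys sumatranus* leaf-extract screen:

```bash
$ metabovote worked-example
shared features (10): Var31, Var42, Var43, Var44, Var45, Var46, Var47, Var48, Var49, Var50
predicted compounds: 9
  m/z 203.180  Var48  unidentified
  m/z 258.244  Var42  unidentified
  m/z 279.232  Var46  15,16-dihydrotanshinone I
  m/z 293.212  Var50  unidentified
  m/z 328.155  Var44+Var49  norisocorydine
  m/z 342.171  Var43  lirioferine
  m/z 423.093  Var45  mangiferin
  m/z 433.114  Var47  apigenin-7-O-galactopyranoside
  m/z 585.145  Var31  neomangiferin
```

Thirteen statistically-selected and seventeen ML-selected features share
exactly 10; two of them (Var44, Var49) carry the same m/z 328.155 and merge,
leaving 9 predicted compounds, six of them identified.

End to end on synthetic data with known truth (actives planted at
Var41–Var50):

```python
from metabovote import PipelineConfig, SyntheticConfig, run_all

result = run_all(PipelineConfig(synthetic=SyntheticConfig(seed=1), seed=1))
print(result.consensus.final_features)
# ['Var41', 'Var42', 'Var43', 'Var44', 'Var45', 'Var46', 'Var47', 'Var48', 'Var49', 'Var50']
print(result.consensus.n_compounds)   # 9  (two planted features share one m/z)
```

On this seed all 24 supervised models pass the gate, both branches select
16 features, and their intersection is exactly the 10 planted actives,
merging to 9 compounds.  The per-method test performance behind the
random-forest choice (same run, no bootstrap):

```
           method  rmse_test   r2_test
linear_regression      1.091    -3.103
    decision_tree      0.526     0.046
    random_forest      0.407     0.428
gradient_boosting      0.478     0.212
        ada_boost      0.424     0.379
```

Other CLI entry points: `simulate` (write a synthetic study as CSVs),
`run-stats`, `run-ml` (one branch at a time), `consensus` (intersect two
selection CSVs), `run-all` (everything plus reports and a run manifest).

## Layout

```
src/metabovote/
  data_model.py     containers, CSV I/O, UV scaling, reciprocal targets, class split
  synthetic.py      study-design generator with planted ground truth
  chemometrics.py   NIPALS PCA/PLS, OPLS, Q², VIP, top-k selection (branch A)
  validity.py       permutation test, CV-ANOVA, three-criterion gate
  ml.py             regressor suite, bootstrap, permutation importance (branch B)
  shapley.py        exact interventional tree Shapley values
  consensus.py      voting, intersection, m/z merge, correlation analyses
  pipeline.py       end-to-end orchestration, manifests, reports
  cli.py            typer command line
  datasets/         bundled case-study tables
docs/methods.md     model assumptions, parameter choices, limitations
```
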