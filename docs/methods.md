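# Methods

`evcohort` re-implements, as a tested pipeline, the statistical workflow of a
small-cohort serum-biomarker study of knee osteoarthritis (KOA): single-EV
subpopulation accounting, univariate group statistics with
false-discovery-rate control, correlated-variable group identification,
unsupervised subject classification, and group-sampling data enrichment with
random-forest (RF) feature-importance ranking. A seeded synthetic-cohort
generator provides the test bed, so every stage is exercised without access
to the original per-subject data.

## Single-EV accounting

Chip-based single-particle imaging (SP-IRIS) captures small EVs on antibody
spots (CD41, CD63, CD81, CD9) and reads per-particle positivity for the
other markers; flow cytometry counts large CD61⁺ EVs by calibrated scatter.
The module consumes pre-called positivity — fluorescence thresholding is the
instrument software's job.

* **Size gates.** Small EVs: diameter in [50, 200] nm; large EVs:
  (200, 1000] nm. The shared 200 nm endpoint is assigned to the sEV gate
  (closed upper bound) and excluded from the lEV gate, so the gates
  partition and no particle is counted twice.
* **Self-positivity.** A particle captured on a tetraspanin spot is positive
  for that marker by construction; ingest enforces this.
* **Co-localization profiles.** Per capture marker, particles are tallied
  over the 8 positivity patterns of the three non-capture markers
  (single-positive, three doubles, three triples, quadruple). Percentages
  use the per-capture denominator, so each capture spot sums to 100%.
  Zero captured particles raise a distinct error ("no data"), because an
  all-negative profile (100% single-positive) is a valid observation.
* **Concentrations.** count × dilution_factor / analyzed_volume_ml, per mL
  of original serum; linear in both count and dilution.
* CD61 is measured on a single scatter channel, so it supports totals and
  concentrations only, not the 4-marker pattern logic.

## Univariate statistics

* **Mann–Whitney U** (control vs KOA): exact null distribution when both
  groups have ≤ 10 observations and the pooled sample is tie-free — the
  regime of an 8-vs-8 cohort — otherwise mid-ranks with the tie-corrected
  normal approximation. The result records which path ran.
* **Kruskal–Wallis** for ≥ 3 groups (control / contralateral / operated
  knee), tie-corrected H on a χ²(k−1) reference.
* **Fisher's exact test** for the 2×2 sex table, two-sided by the
  probability-mass rule (all same-margin tables no more probable than the
  observed one), the convention of major statistics packages.
* **Covariate adjustment**: a Gaussian identity-link linear model
  y ~ intercept + group + covariates, fit by OLS with a Wald test on the
  group coefficient; group × covariate interaction p-values on request.
  The outcomes are continuous, so no other GLM family is warranted.
* **Benjamini–Hochberg**: p-values sorted ascending, p(k) compared with
  α·k/m, rejection of ranks 1..k* where k* is the largest passing rank. The
  report exposes the full threshold ladder and the critical value α·k*/m —
  with m = 38 tests, α = 0.05 and k* = 5 this is 0.00658. When nothing
  rejects, the reported value falls back to α/m with an explicit flag.

## Variable grouping

Pairwise Pearson correlations are computed across all subjects
(pairwise-complete, ≥ 3 paired observations per pair; p-values from the
t transform on n−2 df). Variables are clustered by Ward linkage on the
signed distance d = 1 − r: the structure of interest is blocks of
*positive* correlation, and anticorrelated variables must not co-cluster,
so 1 − |r| is deliberately not used.

The tree is cut into k clusters (default k = 5, a user parameter — no
automatic selection is attempted). Any variable whose mean correlation with
the other members of its cluster is below `residual_threshold` (default
0.4) is moved to a residual group; the remaining core variables are re-cut
and the rule re-applied until no variable moves. The iteration matters:
weakly associated variables otherwise occupy flat-cut slots and force
genuine groups to merge. Singleton clusters count as below threshold.
Variables are processed in name order, making the output independent of
input order; surviving groups are renumbered by their alphabetically first
member.

**Limitation.** With 16 subjects the sampling noise of a correlation
coefficient is large (SE ≈ 0.26 at r = 0); pairs of genuinely unstructured
variables can show r > 0.6 by chance and are then indistinguishable from a
small true group. Recovery of planted structure is therefore exact at large
n but stochastic at n = 16: mean adjusted Rand index ≈ 0.90 over 50 seeds
at the default generator settings (r = 0.8), degrading toward r = 0.7.

## Unsupervised subject classification

Z-scores (per-variable standardization using the sample, n−1, standard
deviation; computed after complete-case exclusion, on the analyzed subset)
feed both analyses. Missing data are never imputed; variables observed in
too few subjects are dropped wholesale and remaining incomplete subjects
excluded, mirroring the exclusion-based strategy of small-cohort studies.

* **PCA** by SVD of the column-centered matrix; no further scaling is
  applied because incoming variables are already unit-variance (re-scaling
  standardized data is idempotent). Scores, orthonormal loadings, and
  non-increasing explained-variance fractions are returned.
* **Hierarchical clustering** of subjects on the correlation distance
  1 − r between subject profiles, with Ward (unsquared distances)
  agglomeration. SciPy's `ward` operates on squared input distances (the
  behavior of R's `ward.D2`), so the unsquared variant hands it
  √d — `ward.D2` on √d has the merge order of `ward.D` on d. A flag
  selects classical squared-distance Ward for comparison. Diagnosis and sex
  are labels only, never features; agreement is scored by adjusted Rand
  index and cluster purity.

## Data enrichment and random forests

A 16-subject cohort cannot support ~38 features, but the variables form a
few strongly intra-correlated groups carrying largely redundant
information. Enrichment exploits this: each replicate draws **one variable
per group, the same choice for every subject** — so the replicate's feature
columns have a coherent meaning — and every subject contributes one
pseudo-subject carrying the sampled Z-scores and its diagnosis label.
Per-pseudo-subject resampling would destroy the feature semantics and is
not offered. 1000 replicates turn 16 subjects into 16,000 pseudo-subjects
over k features (one per core group plus one for the residual group).

Forest hyperparameters follow the fixed recipe: 100 trees, entropy
criterion, max_features = 6 (no restriction on the 6 enriched features, a
genuine restriction on the 38-variable original protocol — both honored as
stated), bootstrap on, unlimited depth. Four protocols:

* `enrich_before_split` — enrich, then split pseudo-subjects 80/20. Train
  and test share source subjects, so near-perfect accuracy (~99.9%) is a
  **structural leakage** result certifying within-group redundancy, not
  generalization.
* `enrich_after_split` — split the 16 subjects 80/20 first, then enrich
  each side with independent variable samplings (no sampled-variable
  information crosses the split). Accuracy here estimates prediction of new
  subjects.
* `original_features` — subject-level split, all variables as features.
* `ev_only` — as above restricted to `ev_marker`-category columns.

Splits are stratified by diagnosis: with 8 + 8 subjects a plain random
80/20 split is frequently single-class. (A bounded retry guard remains for
degenerate inputs.) Per repeat the forest is refit on a fresh split (and
fresh enrichment), and test accuracy plus mean-decrease-in-impurity (MDI)
importances from the training data are averaged — 100 repeats by default.
MDI is only interpretable when the model predicts well, so reports carry a
reliability flag gated on mean accuracy > 0.7 (configurable); the pipeline
skips the importance table when the flag is down. No permutation/SHAP
importance and no hyperparameter search are offered, by scope.

## Synthetic cohort generator

The generator defines the test bed, not a biological claim. Subjects are
drawn from a block-equicorrelated Gaussian: variable j of group g is
√r·L_g + √(1−r)·ε with a per-subject latent L_g, giving within-group
pairwise correlation exactly r (conditional on diagnosis) and ~0 between
groups. The diagnosis effect shifts the latent by effect/√r (± half per
group), so the realized per-variable standardized mean difference equals
the configured effect size. Residual variables are independent noise tagged
with the `ev_marker` category, which lets the EV-only protocol demonstrate
chance-level accuracy on uninformative features. Note that diagnosis
shifts induce *pooled* cross-group correlation between groups whose effects
share a sign (≈ d²/4 / (1 + d²/4)) — exactly the multicollinearity the
enrichment procedure exists to tame, and the reason grouping at n = 16 is
noisy.

Defaults mirror the study design: 8 subjects per diagnosis, 5 groups of 6
variables, 8 residual variables, r = 0.8. Presets:

* `strong-structure` — effects ±2 SD, alternating sign; used for leakage
  and recovery tests.
* `null` — identical structure, zero effects.
* `paper-calibrated` — adds demographic variables matched to the cohort
  (age 64 vs 29 y, BMI 32.2 vs 25.4 kg/m², body mass 90.9 vs 77.9 kg; the
  published standard errors are converted to SDs via SD = SE·√8 for n = 8),
  the observed 2 M/6 F vs 5 M/3 F sex split, and per-diagnosis EV profiles.

EV particle tables are generated per subject and capture channel: Poisson
captured-particle counts, multinomial co-localization patterns, bounded
log-normal diameters. Control pattern probabilities are set to the observed
control percentages (e.g. CD63: 42% single, 32% +CD9, 19% +CD81; CD41: 26%
+CD9, 25% +CD81, 26% +CD63+CD9), with the leftover mass split equally over
the unnamed patterns. Count means (1210–1870 per sample at 10× dilution,
1 µL analyzed) put concentrations on the observed 1.2–1.9 × 10⁷/mL sEV
scale with CD41 most abundant, and 8 × 10⁵/mL for CD61⁺ large EVs. KOA
profiles apply the qualitatively reported shifts (lower CD63⁺/CD9⁺, higher
CD81⁺/CD63⁺ and CD81⁺/CD63⁺/CD9⁺) at modest magnitudes, since only control
percentages are printed.

What the generator does **not** emulate: measurement error structure of the
instruments, non-Gaussian marginals (skewed questionnaire scores, counts),
missing-data mechanisms, subject-level covariate confounding between age/BMI
and the grouped variables, or item-level questionnaire responses. Passing
tests therefore certify the pipeline's statistical machinery under the
stated correlation/effect structure, not clinical validity on real cohorts.

## Randomness and reproducibility

All randomness flows through `numpy.random.default_rng` seeded explicitly;
there is no global RNG state. The pipeline derives stage seeds from the
master seed as `master_seed + stage index` (cohort 0, EV 1, stats 2,
groups 3, cluster 4, RF 5) so stages are independently reproducible; RF
repeats derive per-repeat streams from `SeedSequence([seed, repeat])`.
Identical seeds reproduce every output bit-for-bit, which the manifest
verifies via per-file SHA-256 checksums.

## Problem sizes used by the test suite

The acceptance checks run the leakage protocol at full scale (1000×
enrichment, 100 repeats) and the co-localization recoveries at 10⁵
particles. The surrounding property suites use sizes chosen for a
single-CPU run: leakage-gap calibration at 100 replicates × 4 repeats over
10–12 seeds with moderate effects (|d| = 1, where the before/after contrast
is large); chance-level calibration over 10 seeds; planted-recovery ARI
over 50 seeds at n = 16; type-I error of the exact Mann–Whitney test over
10⁴ null draws; large-n oracle checks at 2000 subjects.

## Known limitations

* Group recovery at n = 16 is stochastic (see above); the residual rule
  (mean within-cluster r < 0.4) is this package's operationalization of
  "weakly associated" — the original analysis published no quantitative
  rule.
* Subject clustering separates the diagnoses perfectly on strongly
  separated cohorts (|d| = 3); at |d| = 2 one borderline subject crosses
  over on a minority of seeds (mean ARI ≈ 0.96).
* The membership of the published variable groups 1–5 is shown only
  graphically in the source study; presets use generic group labels and a
  planted-truth comparator instead.
* `ev_only` inherits the semantics of `original_features`; with 16 subjects
  its accuracy estimates are extremely coarse (test sets of 4).
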