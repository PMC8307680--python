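# Methods

This note documents the statistical model behind `lipidsig`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Data model

The unit of analysis is a samples × metabolites concentration matrix (μmol)
from a targeted, Biocrates-style lipidomics assay of an LDL-depleted serum
sEV fraction, with three balanced donor groups (HC/LN/LC, 81 each) and
96-well preparation plates acting as batches. Every cell carries a
three-state code: observed, below the plate-specific limit of quantitation
(LOQ), or lost to an internal-standard (IS) failure. The two missingness
mechanisms are treated differently throughout because they arise
differently: below-LOQ values are left-censored (the compound is present
but unquantifiable), while IS failures are effectively missing at random.

## Missingness policy

Per compound and group we compute the fraction of each missingness type
over that group's samples. Tier 1 (compounds kept for any analysis)
requires ≤ 50% below-LOQ **and** ≤ 10% IS failures in every group. Tier 2
(the quantitative tier used for differential testing and classification)
requires strictly < 50% below-LOQ in every group. The boundary case —
exactly 50% zeros — is therefore kept at tier 1 but excluded from tier 2;
this reconciles a permissive retention rule ("up to half missing is
allowed") with a strict quantitation rule ("quantified in the majority of
samples"). Compounds failing tier 2 are still analysed qualitatively: their
absent/present status per group enters a χ² independence test (no Yates
correction; tables with > 20% of expected counts below 5 are flagged).

## Imputation

**Below-LOQ.** Censored cells are replaced by draws from a normal
distribution truncated to (0, LOQ(plate, metabolite)). The untruncated
parameterization is unstated in common practice; we centre it at LOQ/2 with
sd LOQ/4, which places the mass mid-interval with negligible boundary
pile-up and makes the truncated mean exactly LOQ/2 by symmetry. Both
fractions are configurable (`trunc_mean_frac`, `trunc_sd_frac`).

**IS failures.** Each failed cell (sample *s*, metabolite *m*) is filled
with the arithmetic mean of *m* in the k = 3 nearest samples, where
distance is 1 − Pearson correlation computed on log2 concentrations over
the metabolites available in both samples (at least 10 shared metabolites,
else the pair is ineligible — correlations on fewer points are unstable).
Candidates must have *m* available and preferentially share both *s*'s
group and plate. Because that restriction can be unsatisfiable at high
missingness, a fallback ladder widens the pool: (1) same group, any plate;
(2) any group, same plate; (3) the metabolite's global mean. The ladder
level used is logged per cell. Values already imputed at the below-LOQ step
count as available: they carry information about the compound's low level.

## Batch correction

Plates are batches. After log2 transformation, per-plate location and scale
effects are estimated per metabolite, shrunk across metabolites by
parametric empirical Bayes (normal prior on locations, inverse-gamma on
scales, moment-matched hyperpriors, iterative fixed-point solve at 1e-4
relative tolerance), and removed — the standard parametric ComBat
algorithm, implemented here directly and verified against Bioconductor
`sva::ComBat` to < 1e-10 on a fixed fixture. The group label is included as
a covariate in the location model by default (`protect_group=True`) so that
group differences survive correction even under group-imbalanced plate
layouts; the flag can be disabled to reproduce an unprotected correction.
A single-plate panel is returned unchanged — there is no batch to remove.
Empirical-Bayes shrinkage removes planted uniform plate shifts down to
plate-mean residuals of a few hundredths of a log2 unit at realistic batch
sizes; the irreducible floor is the sampling noise of per-plate means.

## Normalization and aggregation

Because vesicle counts are not available, compound levels are expressed as
permille (‰) of the sample's total concentration over the quantitative
tier; rows sum to 1000 exactly. Permille shares are scale-invariant per
sample, which removes the dominant inter-individual "lipid load" component.
Class-level summaries aggregate raw concentrations per lipid class and
report each class's percentage of the sample total.

## Differential abundance

All tests are rank-based and therefore invariant under strictly monotone
transforms. The omnibus screen is the tie-corrected Kruskal–Wallis test;
its effect size is the standard eta-squared η² = (H − k + 1)/(n − k),
clipped at 0. Pairwise comparisons use the Conover–Iman statistic with the
pooled tie-corrected rank variance S² = (ΣR² − n(n+1)²/4)/(n−1) and the
(n−1−H)/(n−k) correction, two-sided p from Student's t with n − k degrees
of freedom. The standardized effect is r = |t|/√(n_i + n_j); the
denominator is configurable (√n as the alternative reading of
"standardized by the square root of the sample's size"). Fold-changes are
ratios of group medians on the permille scale. Benjamini–Hochberg
adjustment is applied separately within each family (omnibus; each group
pair; the presence family). Reporting is gatekept: pairwise findings are
interpreted only for compounds passing the omnibus screen, and raw-p
findings are reported with adjusted q alongside. Constant compounds yield
H = 0, p = 1 with a flag rather than an error.

## Signature search

The classifier is a maximum-likelihood multinomial logistic model (first
declared class as reference; BIC = −2·loglik + p·ln n with
p = (features+1)(classes−1)). It is fitted by a small Newton solver with a
ridge penalty of 1e-6 on the slopes — excluded from the BIC parameter
count — so that separable teaching subsets yield finite coefficients
instead of crashing the search; fits in the ridge-dominated regime are
flagged. The fit was cross-checked against statsmodels' MNLogit to 1e-6 on
a fixed fixture.

The discovery procedure is nested to keep test estimates honest:

* **Outer loop:** 8 folds; each draws 8 test samples per group, without
  replacement and non-overlapping across folds (with 81 per group, 17 per
  group are never tested but stay in every training set). If a group is too
  small, the per-group test count is reduced with a warning.
* **Inner loop (MRCV):** 100 stratified 70/30 teaching/testing splits of
  the fold's training remainder. On each teaching part, greedy forward
  selection adds the BIC-minimizing candidate while the improvement exceeds
  ΔBIC = 2; ties break by fixed column order; candidates whose fit fails
  (exact collinearity) are skipped. Teaching and testing MAP accuracies are
  recorded per repeat.
* **Ranking and elbow:** features are ranked by selection frequency
  (descending), then mean forward-addition order (ascending), then id; the
  ranked frequency curve is cut at its largest consecutive drop. The fold
  model is refitted on the whole training remainder with the elbow set.
* **Metrics:** overall accuracy under MAP classification (binary models
  instead threshold P(positive) at the Youden-J maximizer computed on
  training scores, ties resolved to the midpoint of the tied interval);
  AUC is the trapezoidal ROC area for binary models and macro-averaged
  one-vs-rest for three classes (Hand–Till is available via config — the
  multi-class AUC definition is genuinely open); per-class sensitivity and
  specificity from the confusion matrix. Fold metrics are aggregated as
  means with t-distribution 95% CIs (folds − 1 df).
* **Final model:** the elbow of the ranking pooled over all folds' MRCV
  models, refitted on all samples. The elbow size is reported rather than
  forced to a fixed signature length.

Features enter on the permille scale by default (`feature_scale="log2"`
switches to the batch-corrected matrix). When a candidate cap is set
(`max_candidate_features`), candidates are pre-screened by the
Kruskal–Wallis p computed **within the training samples only**, so no test
information leaks into selection.

The whole procedure is a pure function of (panel, config, seed); all
randomness flows through `numpy.random.SeedSequence` spawns.

## Synthetic-data generator

Per compound, log2 concentration = class mean + compound offset
(sd `class_log2_sd` = 1) + per-plate shift (sd `plate_shift_sd` = 0.3) +
per-sample heterogeneity shared across compounds (sd 0.3) + residual noise
(sd 0.35 log2 ≈ 25% CV). Class means are set so cholesteryl esters carry
roughly two thirds of the total mass and choline phospholipids about a
quarter, as in an LDL-depleted sEV fraction. Planted effects multiply the
affected group's concentrations **before** missingness injection, keeping
the fold-change oracle clean. Per-plate LOQs sit at the 2.5% quantile of
each compound's generating distribution, so zeros arise mechanistically
from truncation as well as from an explicit per-compound rate; a
configurable fraction of "poorly detected" compounds (default 151/352)
receives high zero rates (0.55–0.95), which reproduces a panel in which
roughly 201 of 352 compounds pass the quantitative tier. Missingness rates
are identical across groups so that null panels carry no label signal in
the missingness pattern. An optional within-class correlation parameter
adds per-sample, per-class factors to the residuals (no value is asserted
for it; real lipid classes are strongly co-regulated, and the
kNN-imputation masking experiment uses 0.6 for exactly that reason).

**What the generator does not emulate:** inter-class correlation beyond the
shared load factor, covariate structure (age, sex, smoking), compartment
coupling (sEV vs whole serum panels are generated independently),
non-log-normal tails, and plate layouts confounded with enrolment. Passing
tests therefore demonstrate correctness and calibration of the *procedure*
under a realistic null and under planted effects of realistic magnitude —
not that any particular real cohort would yield a signature.

## Problem sizes used in the test suite

The chance-calibration check runs the full nested pipeline on 10 null
panels of 3 × 81 samples with MRCV reduced to 25 repeats and candidates
capped at 50 (about 20 s per panel); the selection-sanity check uses 10
study-scale panels with 200 compounds, 40 MRCV repeats and 5 planted
effects of magnitude 1.2–1.7× placed on complementary group contrasts —
five same-direction effects on one group would be largely redundant for a
multinomial model, and greedy ΔBIC selection would (correctly) stop early.
The batch-correction recovery check uses 40 samples/group, 30 compounds and
low residual noise so that the empirical-Bayes shrinkage floor (sampling
noise of plate means) stays well below the 0.05 log2 acceptance bound.

## Known limitations

* The Conover implementation assumes the omnibus H from the same data;
  pairwise p-values for compounds failing the omnibus screen are reported
  but should not be interpreted (gatekeeping is enforced in `significant()`).
* The empirical-Bayes correction assumes enough metabolites (dozens) for
  stable hyperprior estimation; tiny panels fall back on essentially
  unshrunk estimates.
* Youden thresholds are chosen on training data only; with small test sets
  the binary test AUCs have wide CIs, mirroring the behaviour of such
  procedures at n ≈ 81 per group.
* UMAP coordinates are descriptive only; silhouette scores in embedding
  space are reported for qualitative "no group separation" statements, not
  as a test statistic.
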