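# lipidsig

Analysis pipeline for targeted lipidomics panels from serum small
extracellular vesicles (sEV) in a three-group cancer-screening setting:
healthy controls (HC), participants with benign lung nodules (LN), and
patients with screening-detected lung cancer (LC).

Concentration panels from targeted assays come with two kinds of missing
values — "zeros" below a plate-specific limit of quantitation (LOQ) and
measurements lost to internal-standard (IS) failures — and with per-plate
batch effects. `lipidsig` implements the full chain from such a raw panel to
differential-abundance tables and a cross-validated multivariate signature:

1. **Missingness policy** — a compound is retained iff, in every group, at
   most 50% of its values are below-LOQ and at most 10% are IS failures;
   the *quantitative tier* additionally requires strictly less than 50%
   zeros in every group.
2. **Dual imputation** — below-LOQ cells are drawn from a normal
   distribution truncated to (0, LOQ) for the cell's plate; IS failures are
   filled by the mean of the k = 3 nearest samples under correlation
   distance (1 − Pearson r over shared compounds), preferring samples from
   the same group and plate.
3. **Batch correction** — parametric empirical-Bayes location/scale
   adjustment of per-plate effects on log2 concentrations (plates are
   batches; the group label is protected as a covariate).
4. **Permille normalization** — each compound expressed as ‰ of the
   sample's total lipid concentration (a substitute for unavailable vesicle
   counts), plus lipid-class aggregation.
5. **Differential abundance** — Kruskal–Wallis omnibus screen with
   η² = (H − k + 1)/(n − k), Conover–Iman pairwise post hoc tests with the
   standardized effect r = |t|/√(n_i + n_j), median-based fold-changes,
   Benjamini–Hochberg adjustment per family, a χ² presence/absence analysis
   for excluded compounds, and a two-compartment (e.g. sEV vs whole serum)
   comparison table.
6. **Signature search** — nested cross-validation: 8 outer folds each
   extract 8 test samples per group; on the remainder, 100 stratified 70/30
   teaching/testing splits (multiple random cross-validation) each run
   greedy forward selection for a multinomial logistic model with the stop
   rule ΔBIC ≤ 2; features are ranked by selection frequency and mean
   addition order, the ranking is cut at its largest frequency drop (elbow),
   and the fold model is refitted and scored (accuracy, AUC, per-class
   sensitivity/specificity; MAP classification, or a Youden-J threshold for
   binary models) with t-based 95% CIs over folds.

A synthetic-data generator reproduces the statistical structure of such a
cohort (log-normal concentrations with per-class levels, plate shifts,
strong inter-individual heterogeneity, both missingness mechanisms, planted
multiplicative group effects), so the whole pipeline is testable without
access to clinical raw data.

## Worked example

```python
import lipidsig as L

cfg = L.SimulationConfig(seed=11)          # 3 x 81 samples, 352 compounds
panel = L.generate_panel(cfg)
config = L.AnalysisConfig(mrcv_repeats=25, max_candidate_features=50, seed=11)

policy, norm = L.preprocess_panel(panel, config)
print(len(policy.retained_all), len(policy.retained_quant))
# 201 201

res = L.SignatureCV.from_normalized(norm, config=config).fit(seed=11)
print(res.summary())
```

```
Nested cross-validated signature search
============================================
classes:           HC, LN, LC
samples:           243
features offered:  201
outer folds:       8 (8 test samples per group)
MRCV repeats/fold: 25
signature sizes:   1-2
final signature (1 features): CE(14:1)

metric                mean  95% CI
train_accuracy       0.410  (0.391, 0.429)
test_accuracy        0.349  (0.300, 0.398)
train_auc            0.581  (0.565, 0.596)
test_auc             0.493  (0.441, 0.544)
```

This panel carries no planted group effects, so the signature search finds
nothing real: the test-accuracy CI covers the three-class chance rate of
33.3%, test AUC sits at 0.5, training metrics exceed test metrics (the
usual selection-induced optimism), and the tiny "signatures" are noise —
the expected behaviour of an honest nested procedure on null data. Planting effects via
`SimulationConfig(effects=(L.PlantedEffect("PC(30:0)", "LC", 1.326), ...))`
makes the differential screen and the signature search recover them (see
`tests/test_acceptance.py`).

A command-line interface mirrors the stages:

```sh
lipidsig simulate --config sim.yaml --seed 7 --out panel/
lipidsig preprocess panel/ --out results/
lipidsig diffstats panel/ --serum-panel serum_panel/ --out results/
lipidsig classify panel/ --seed 7 --out results/
lipidsig report panel/ --seed 7 --out results/
```

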