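import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidsig import AnalysisConfig, SimulationConfig, generate_panel
from lipidsig.errors import BatchCorrectionError, NormalizationError, PolicyError
from lipidsig.panel import MetabolitePanel, MissingCode
from lipidsig.preprocess import (
    aggregate_classes,
    apply_missingness_policy,
    combat,
    impute_below_loq,
    impute_knn,
    log2_and_batch_correct,
    normalize_permille,
    preprocess_panel,
)


def make_panel(conc, codes, groups, plates, classes, loq, group_order=None):
    """Assemble a small panel from plain arrays."""
    conc = np.asarray(conc, dtype=float)
    n, m = conc.shape
    sample_ids = [f"S{i}" for i in range(n)]
    met_ids = [f"{classes[j]}(3{j}:0)" for j in range(m)]
    metabolites = pd.DataFrame({"class": classes},
                               index=pd.Index(met_ids, name="metabolite_id"))
    for p in sorted(set(plates)):
        metabolites[f"LOQ_{p}"] = loq
    return MetabolitePanel(
        concentrations=pd.DataFrame(conc, index=sample_ids, columns=met_ids),
        codes=pd.DataFrame(np.asarray(codes, dtype=np.int8),
                           index=sample_ids, columns=met_ids),
        samples=pd.DataFrame({"group": groups, "plate": plates},
                             index=pd.Index(sample_ids, name="sample_id")),
        metabolites=metabolites,
        group_order=tuple(group_order or pd.unique(np.asarray(groups, dtype=object))),
    )


# ----------------------------------------------------------------------
# policy
# ----------------------------------------------------------------------

class TestMissingnessPolicy:
    def _panel(self, zero_fracs):
        """10 samples per group x len(zero_fracs) compounds; compound j has
        the requested below-LOQ fraction in group A and none in group B."""
        n_per = 10
        m = len(zero_fracs)
        conc = np.ones((2 * n_per, m))
        codes = np.zeros((2 * n_per, m), dtype=int)
        for j, f in enumerate(zero_fracs):
            k = int(round(f * n_per))
            codes[:k, j] = int(MissingCode.BELOW_LOQ)
        conc[codes != 0] = np.nan
        return make_panel(conc, codes, ["A"] * n_per + ["B"] * n_per,
                          ["P1"] * 2 * n_per, ["PC"] * m, [0.1] * m)

    def test_tier_boundaries(self):
        # 60% zeros -> excluded; exactly 50% -> tier 1 kept, tier 2 dropped;
        # fully observed -> kept at both tiers
        panel = self._panel([0.6, 0.5, 0.0])
        res = apply_missingness_policy(panel, AnalysisConfig())
        sixty, fifty, clean = panel.concentrations.columns
        assert sixty in res.excluded
        assert fifty in res.retained_all and fifty not in res.retained_quant
        assert clean in res.retained_all and clean in res.retained_quant

    def test_is_failure_ceiling(self):
        panel = self._panel([0.0])
        codes = panel.codes.to_numpy()
        codes[:2, 0] = int(MissingCode.IS_FAILURE)  # 20% in group A > 10%
        panel.concentrations.iloc[:2, 0] = np.nan
        res = apply_missingness_policy(panel, AnalysisConfig())
        assert panel.concentrations.columns[0] in res.excluded
        assert "IS-failure" in list(res.excluded.values())[0]

    def test_partition_invariants(self, small_panel):
        res = apply_missingness_policy(small_panel, AnalysisConfig())
        all_ids = set(small_panel.concentrations.columns)
        assert set(res.retained_quant) <= set(res.retained_all)
        assert set(res.retained_all) | set(res.excluded) == all_ids
        assert not set(res.retained_all) & set(res.excluded)

    def test_empty_group_raises(self):
        panel = self._panel([0.0])
        panel.group_order = ("A", "B", "C")  # C declared but empty
        with pytest.raises(PolicyError, match="C"):
            apply_missingness_policy(panel, AnalysisConfig())


# ----------------------------------------------------------------------
# below-LOQ imputation
# ----------------------------------------------------------------------

class TestBelowLoqImputation:
    def test_support_and_determinism(self, small_panel):
        res = apply_missingness_policy(small_panel)
        a = impute_below_loq(small_panel, res.retained_all, seed=3)
        b = impute_below_loq(small_panel, res.retained_all, seed=3)
        assert a.concentrations.equals(b.concentrations)
        c = impute_below_loq(small_panel, res.retained_all, seed=4)
        below = a.codes[res.retained_all].to_numpy() == int(MissingCode.BELOW_LOQ)
        if below.any():
            assert not np.array_equal(
                a.concentrations[res.retained_all].to_numpy()[below],
                c.concentrations[res.retained_all].to_numpy()[below],
            )
        loq = a.loq_matrix()[res.retained_all].to_numpy()
        vals = a.concentrations[res.retained_all].to_numpy()
        assert np.all(vals[below] > 0)
        assert np.all(vals[below] < loq[below])

    def test_monte_carlo_mean_matches_truncated_normal(self):
        """10,000 draws at LOQ L center on L/2 (the truncated-normal mean
        under the symmetric default parameterization) within 3 SE."""
        L = 0.08
        n = 10_000
        conc = np.full((n, 1), np.nan)
        codes = np.full((n, 1), int(MissingCode.BELOW_LOQ))
        panel = make_panel(conc, codes, ["A"] * n, ["P1"] * n, ["PC"], [L])
        out = impute_below_loq(panel, seed=9)
        draws = out.concentrations.to_numpy().ravel()
        # closed form: symmetric truncation at +-2 sd around L/2 -> mean L/2
        a, b = -2.0, 2.0
        sd_z = np.sqrt(stats.truncnorm.var(a, b))
        se = (L / 4) * sd_z / np.sqrt(n)
        assert abs(draws.mean() - L / 2) < 3 * se
        assert draws.min() > 0 and draws.max() < L


# ----------------------------------------------------------------------
# kNN imputation
# ----------------------------------------------------------------------

class TestKnnImputation:
    def _neighbour_panel(self, target_vals=(2.0, 4.0, 6.0), far_val=100.0):
        """Sample S0 has an IS failure at the last compound; three samples
        share its profile exactly (distance 0) and carry the target values;
        one distant sample carries far_val."""
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 5, size=12)
        rows = [np.r_[base, np.nan]]
        for v in target_vals:
            rows.append(np.r_[base * 1.5, v])  # perfectly correlated with S0
        rows.append(np.r_[rng.uniform(1, 5, size=12), far_val])
        conc = np.array(rows)
        codes = np.zeros_like(conc, dtype=int)
        codes[0, -1] = int(MissingCode.IS_FAILURE)
        n = len(rows)
        return make_panel(conc, codes, ["A"] * n, ["P1"] * n,
                          ["PC"] * 13, [0.01] * 13)

    def test_mean_of_three_nearest(self):
        panel = self._neighbour_panel()
        out, log = impute_knn(panel, k=3)
        assert out.concentrations.iloc[0, -1] == pytest.approx(4.0)
        assert log.iloc[0]["fallback_level"] == 0

    def test_duplicate_profile_is_selected_first(self):
        panel = self._neighbour_panel(target_vals=(2.0,))
        out, _ = impute_knn(panel, k=1)
        assert out.concentrations.iloc[0, -1] == pytest.approx(2.0)

    def test_fallback_to_global_mean(self):
        # every other sample also fails at the same compound except one
        panel = self._neighbour_panel()
        codes = panel.codes.to_numpy()
        codes[1:-1, -1] = int(MissingCode.IS_FAILURE)
        conc = panel.concentrations.to_numpy()
        conc[1:-1, -1] = np.nan
        panel.concentrations.iloc[:, :] = conc
        out, log = impute_knn(panel, k=3)
        # only the "far" sample remains; too few shared metabolites never
        # applies here, so it is found at ladder level 0
        assert out.concentrations.iloc[0, -1] == pytest.approx(100.0)

    def test_masking_experiment_beats_global_mean(self):
        """Hiding 5% of observed cells: correlation-kNN recovers them with
        lower log2 RMSE than per-metabolite global-mean imputation."""
        cfg = SimulationConfig(
            n_per_group=20, n_metabolites=120, n_plates=2,
            zero_missing_rate=0.0, is_missing_rate=0.0,
            poorly_detected_fraction=0.0, loq_quantile=0.0,
            within_class_correlation=0.6, plate_shift_sd=0.6, seed=0,
        )
        panel = generate_panel(cfg)
        rng = np.random.default_rng(1000)
        mask = rng.random(panel.concentrations.shape) < 0.05
        truth = panel.concentrations.to_numpy().copy()
        arr = panel.concentrations.to_numpy()
        arr[mask] = np.nan
        codes = panel.codes.to_numpy()
        codes[mask] = int(MissingCode.IS_FAILURE)
        imp, _ = impute_knn(panel, k=3)
        knn_rmse = np.sqrt(np.mean(
            (np.log2(imp.concentrations.to_numpy()[mask]) - np.log2(truth[mask])) ** 2
        ))
        colmean = np.nanmean(arr, axis=0)
        mean_rmse = np.sqrt(np.mean(
            (np.log2(colmean[np.where(mask)[1]]) - np.log2(truth[mask])) ** 2
        ))
        assert knn_rmse < mean_rmse


# ----------------------------------------------------------------------
# batch correction
# ----------------------------------------------------------------------

class TestBatchCorrection:
    def test_single_plate_is_identity(self, clean_panel):
        sub = clean_panel.samples["plate"] == clean_panel.samples["plate"].iloc[0]
        panel = MetabolitePanel(
            concentrations=clean_panel.concentrations[sub],
            codes=clean_panel.codes[sub],
            samples=clean_panel.samples[sub],
            metabolites=clean_panel.metabolites,
            group_order=clean_panel.group_order,
        )
        out = log2_and_batch_correct(panel)
        assert np.allclose(
            out.to_numpy(), np.log2(panel.concentrations.to_numpy()), atol=1e-8
        )

    def test_planted_plate_shift_removed(self):
        """A uniform +1.0 log2 shift planted on plate B is removed down to
        plate-mean residuals below 0.05 log2 units per metabolite."""
        cfg = SimulationConfig(
            n_per_group=40, n_metabolites=30, n_plates=2,
            plate_shift_sd=0.0, residual_log2_sd=0.10, heterogeneity_sd=0.05,
            zero_missing_rate=0.0, is_missing_rate=0.0,
            poorly_detected_fraction=0.0, loq_quantile=0.0, seed=1,
        )
        panel = generate_panel(cfg)
        shift_rows = (panel.samples["plate"] == "P2").to_numpy()
        panel.concentrations.iloc[shift_rows, :] *= 2.0  # +1.0 on log2
        out = log2_and_batch_correct(panel)
        means_a = out[~shift_rows].mean(axis=0)
        means_b = out[shift_rows].mean(axis=0)
        assert np.abs(means_a - means_b).max() < 0.05

    def test_orthogonal_group_effect_preserved(self, clean_config):
        from lipidsig import PlantedEffect

        target = "PC(30:0)"
        cfg = clean_config.replace(
            effects=(PlantedEffect(target, "LC", 2.0),), seed=13
        )
        panel = generate_panel(cfg)
        groups = panel.samples["group"].to_numpy()
        log2_raw = np.log2(panel.concentrations[target].to_numpy())
        pre = log2_raw[groups == "LC"].mean() - log2_raw[groups == "HC"].mean()
        out = log2_and_batch_correct(panel)
        vals = out[target].to_numpy()
        post = vals[groups == "LC"].mean() - vals[groups == "HC"].mean()
        assert post == pytest.approx(pre, rel=0.10)

    def test_tiny_plate_rejected(self, clean_panel):
        panel = clean_panel.copy()
        panel.samples.iloc[0, panel.samples.columns.get_loc("plate")] = "P3"
        panel.metabolites["LOQ_P3"] = panel.metabolites["LOQ_P1"]
        with pytest.raises(BatchCorrectionError, match="fewer than 2"):
            log2_and_batch_correct(panel)

    def test_matches_reference_empirical_bayes_fit(self):
        """Frozen fixture computed once with an independent empirical-Bayes
        batch-correction implementation (Bioconductor sva::ComBat 3.50,
        parametric priors, group covariate protected)."""
        from _combat_fixture import COMBAT_INPUT, COMBAT_EXPECTED

        data = pd.DataFrame(COMBAT_INPUT.T)  # samples x features
        batch = pd.Series([1] * 5 + [2] * 5)
        covs = pd.get_dummies(pd.Series(list("ABABABABAB")),
                              drop_first=True, dtype=float)
        out = combat(data, batch, covs)
        assert np.abs(out.to_numpy() - COMBAT_EXPECTED.T).max() < 1e-10


# ----------------------------------------------------------------------
# permille + class aggregation
# ----------------------------------------------------------------------

class TestPermille:
    def test_half_total_is_500(self):
        df = pd.DataFrame({"a": [2.0], "b": [1.0], "c": [1.0]})
        out = normalize_permille(df)
        assert out.loc[0, "a"] == pytest.approx(500.0)

    def test_scale_invariance_and_row_sums(self, clean_panel):
        conc = clean_panel.concentrations
        out1 = normalize_permille(conc)
        out2 = normalize_permille(conc * 2.0)
        assert np.allclose(out1.to_numpy(), out2.to_numpy())
        assert np.allclose(out1.sum(axis=1).to_numpy(), 1000.0, rtol=1e-9)

    def test_three_to_one_ratio(self):
        df = pd.DataFrame({"a": [3.0], "b": [1.0]})
        out = normalize_permille(df)
        assert out.loc[0, "a"] == pytest.approx(750.0)
        assert out.loc[0, "b"] == pytest.approx(250.0)

    def test_zero_total_rejected(self):
        df = pd.DataFrame({"a": [0.0], "b": [0.0]})
        with pytest.raises(NormalizationError, match="zero total"):
            normalize_permille(df)


class TestClassAggregation:
    def test_single_class_total_equals_sample_total(self):
        imputed = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        classes = pd.Series(["PC", "PC"], index=["a", "b"])
        out = aggregate_classes(imputed=imputed, classes=classes)
        assert np.allclose(out["PC"], imputed.sum(axis=1))
        assert np.allclose(out["PC_pct"], 100.0)

    def test_contributions_sum_to_100(self, clean_panel):
        imputed = clean_panel.concentrations
        classes = clean_panel.metabolites["class"]
        out = aggregate_classes(imputed=imputed, classes=classes)
        pct = out[[c for c in out.columns if c.endswith("_pct")]]
        assert np.allclose(pct.sum(axis=1), 100.0)

    def test_dominant_class_share_recovered(self):
        # CE built to carry 2/3 of the total mass
        imputed = pd.DataFrame({"ce1": [4.0, 8.0], "pc1": [1.0, 2.0],
                                "pc2": [1.0, 2.0]})
        classes = pd.Series(["CE", "PC", "PC"], index=imputed.columns)
        out = aggregate_classes(imputed=imputed, classes=classes)
        assert np.allclose(out["CE_pct"], 100 * 2 / 3)


# ----------------------------------------------------------------------
# full chain
# ----------------------------------------------------------------------

def test_full_chain_is_deterministic_and_complete(small_panel):
    cfg = AnalysisConfig(seed=5)
    pol1, norm1 = preprocess_panel(small_panel, cfg)
    pol2, norm2 = preprocess_panel(small_panel, cfg)
    assert norm1.imputed.equals(norm2.imputed)
    assert norm1.log2bc.equals(norm2.log2bc)
    assert norm1.permille.equals(norm2.permille)
    assert not norm1.imputed.isna().any().any()
    # provenance conserved: flags match the original code matrix
    assert norm1.provenance.equals(small_panel.codes[pol1.retained_all])
    # batch correction never alters counts
    assert norm1.log2bc.shape == norm1.imputed.shape
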