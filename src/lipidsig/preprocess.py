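"""Panel preprocessing chain.

The fixed order of operations is: missingness policy → below-LOQ
(truncated-normal) imputation → correlation-kNN imputation of
internal-standard failures → log2 transform → empirical-Bayes batch
correction; permille normalization operates on the (unlogged) imputed
concentrations of the quantitative tier.  Re-running with the same seed is
bit-identical.

Two policy tiers mirror the usual practice for targeted panels:

* tier 1 ("retained_all"): a compound is kept iff, in every group, at most
  50% of values are below-LOQ *and* at most 10% are internal-standard
  failures — otherwise it is excluded from all further analyses;
* tier 2 ("retained_quant"): quantitative compounds additionally need
  strictly less than 50% below-LOQ values in every group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import (
    BatchCorrectionError,
    ImputationError,
    NormalizationError,
    PolicyError,
)
from .panel import MetabolitePanel, MissingCode


# ----------------------------------------------------------------------
# missingness policy
# ----------------------------------------------------------------------

@dataclass
class MissingnessPolicyResult:
    """Outcome of the two-tier missingness policy."""

    retained_all: list[str]
    retained_quant: list[str]
    excluded: dict[str, str]  # metabolite id -> violated rule
    fractions: pd.DataFrame   # group x metabolite missing fractions by type

    def summary(self) -> pd.DataFrame:
        rows = [
            {"tier": "retained_all", "n": len(self.retained_all)},
            {"tier": "retained_quant", "n": len(self.retained_quant)},
            {"tier": "excluded", "n": len(self.excluded)},
        ]
        return pd.DataFrame(rows)


def apply_missingness_policy(
    panel: MetabolitePanel, config: AnalysisConfig | None = None
) -> MissingnessPolicyResult:
    """Classify every compound into the two retention tiers.

    Fractions are computed per group over that group's samples.  Tier 1 uses
    ``<=`` on both ceilings (50% zeros and 10% IS failures are still
    allowed); the quantitative tier 2 requires strictly ``<`` the zero
    ceiling in every group.
    """
    config = config or AnalysisConfig()
    counts = panel.samples["group"].value_counts()
    for g in panel.group_order:
        if counts.get(g, 0) == 0:
            raise PolicyError(f"group {g!r} has zero samples")
    frac = panel.missing_fractions()
    by_met = frac.groupby("metabolite", sort=False)
    max_zero = by_met["frac_below_loq"].max()
    max_is = by_met["frac_is_failure"].max()

    retained_all, retained_quant, excluded = [], [], {}
    for met in panel.concentrations.columns:
        z, i = max_zero[met], max_is[met]
        if z > config.zero_missing_ceiling:
            excluded[met] = (
                f"below-LOQ fraction {z:.3f} exceeds ceiling "
                f"{config.zero_missing_ceiling:.2f} in at least one group"
            )
        elif i > config.is_missing_ceiling:
            excluded[met] = (
                f"IS-failure fraction {i:.3f} exceeds ceiling "
                f"{config.is_missing_ceiling:.2f} in at least one group"
            )
        else:
            retained_all.append(met)
            if z < config.quantitative_zero_ceiling:
                retained_quant.append(met)
    return MissingnessPolicyResult(retained_all, retained_quant, excluded, frac)


# ----------------------------------------------------------------------
# imputation
# ----------------------------------------------------------------------

def impute_below_loq(
    panel: MetabolitePanel,
    retained: list[str] | None = None,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> MetabolitePanel:
    """Replace below-LOQ cells with truncated-normal draws on ``(0, LOQ)``.

    The untruncated normal is centred at ``trunc_mean_frac * LOQ`` with sd
    ``trunc_sd_frac * LOQ`` (defaults LOQ/2 and LOQ/4), truncated to the
    segment between 0 and the limit of quantitation of the cell's plate.
    Observed cells are untouched; draws are reproducible from ``seed``.
    """
    config = config or AnalysisConfig()
    out = panel.copy()
    cols = list(retained) if retained is not None else list(out.concentrations.columns)
    codes = out.codes[cols].to_numpy()
    mask = codes == int(MissingCode.BELOW_LOQ)
    if not mask.any():
        return out
    loq = out.loq_matrix()[cols].to_numpy()
    cell_loq = loq[mask]
    if not np.all(np.isfinite(cell_loq) & (cell_loq > 0)):
        i, j = [a[0] for a in np.where(mask & ~(np.isfinite(loq) & (loq > 0)))]
        raise ImputationError(
            f"missing or non-positive LOQ for metabolite {cols[j]!r} on plate "
            f"{out.samples['plate'].iloc[i]!r}"
        )
    # same standardized truncation bounds for every cell: a=-mu/sd, b=(LOQ-mu)/sd
    a = -config.trunc_mean_frac / config.trunc_sd_frac
    b = (1.0 - config.trunc_mean_frac) / config.trunc_sd_frac
    rng = np.random.default_rng(seed)
    z = stats.truncnorm.rvs(a, b, size=int(mask.sum()), random_state=rng)
    draws = cell_loq * (config.trunc_mean_frac + config.trunc_sd_frac * z)
    block = out.concentrations[cols].to_numpy()
    block[mask] = draws
    out.concentrations.loc[:, cols] = block
    return out


def _pairwise_correlation(log2: pd.DataFrame, min_shared: int) -> pd.DataFrame:
    """Sample-sample Pearson correlation on log2 values over the metabolites
    available in both samples; pairs sharing fewer than ``min_shared``
    metabolites get NaN (ineligible)."""
    return log2.T.corr(min_periods=min_shared)


def impute_knn(
    panel: MetabolitePanel,
    retained: list[str] | None = None,
    k: int = 3,
    config: AnalysisConfig | None = None,
) -> tuple[MetabolitePanel, pd.DataFrame]:
    """Fill internal-standard failures by correlation-distance kNN.

    For a failed cell (sample ``s``, metabolite ``m``) the candidates are the
    samples with ``m`` available, ranked by correlation distance
    ``1 - Pearson r`` computed on log2 concentrations over the metabolites
    available in both samples.  Candidates from the same group *and* plate as
    ``s`` are preferred; when fewer than ``k`` exist the pool widens in the
    order (same group, any plate) → (any group, same plate); if no eligible
    neighbour remains the metabolite's global mean is used.  The imputed
    value is the arithmetic mean of the ``k`` nearest candidates' values.

    Returns the imputed panel and a per-cell log of the fallback level used
    (0 = in-group/in-plate only, 1/2 = widened pool, 3 = global mean).
    """
    config = config or AnalysisConfig()
    out = panel.copy()
    cols = list(retained) if retained is not None else list(out.concentrations.columns)
    codes = out.codes[cols]
    conc = out.concentrations[cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(conc.where(conc > 0))
    corr = _pairwise_correlation(log2, config.min_shared_metabolites)

    groups = out.samples["group"]
    plates = out.samples["plate"]
    values = conc.to_numpy()
    code_arr = codes.to_numpy()
    sample_index = conc.index
    log_rows = []

    fail_cells = np.argwhere(code_arr == int(MissingCode.IS_FAILURE))
    for i, j in fail_cells:
        s = sample_index[i]
        available = code_arr[:, j] != int(MissingCode.IS_FAILURE)
        available[i] = False
        dist = 1.0 - corr.iloc[i].to_numpy()
        eligible = available & np.isfinite(dist)
        same_group = (groups == groups.iloc[i]).to_numpy()
        same_plate = (plates == plates.iloc[i]).to_numpy()
        # priority ladder: 0 in-group/in-plate, 1 in-group, 2 in-plate
        level_masks = [
            eligible & same_group & same_plate,
            eligible & same_group & ~same_plate,
            eligible & ~same_group & same_plate,
        ]
        chosen: list[int] = []
        level_used = 0
        for level, mask in enumerate(level_masks):
            cand = np.flatnonzero(mask)
            if cand.size:
                cand = cand[np.argsort(dist[cand], kind="stable")]
                take = min(k - len(chosen), cand.size)
                chosen.extend(cand[:take].tolist())
                level_used = level
            if len(chosen) >= k:
                break
        if chosen:
            values[i, j] = float(np.mean(values[chosen, j]))
        else:
            pool = values[available, j]
            if pool.size == 0:
                raise ImputationError(
                    f"no candidate neighbours for sample {s!r}, metabolite "
                    f"{cols[j]!r} after all fallbacks"
                )
            values[i, j] = float(np.mean(pool))
            level_used = 3
        log_rows.append(
            {"sample_id": s, "metabolite": cols[j], "fallback_level": level_used,
             "n_neighbors": len(chosen) if chosen else 0}
        )

    out.concentrations.loc[:, cols] = values
    log = pd.DataFrame(
        log_rows, columns=["sample_id", "metabolite", "fallback_level", "n_neighbors"]
    )
    return out, log


# ----------------------------------------------------------------------
# empirical-Bayes batch correction (parametric, location/scale)
# ----------------------------------------------------------------------

def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a_prior, b_prior, conv=1e-4):
    """Iterative fixed-point solve for the EB-shrunk batch effects."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max()
            if np.abs(g_old).max() > 0 else 0.0,
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat(
    data: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch correction.

    ``data`` is samples x features (already log-transformed).  Per-feature
    batch location and scale effects are estimated, shrunk across features
    via parametric empirical Bayes (normal prior on locations, inverse-gamma
    on scales), and removed.  ``covariates`` (e.g. group dummies) are kept in
    the location model so biological structure is preserved.  With a single
    batch the data are returned unchanged.
    """
    batches = list(pd.unique(batch))
    if len(batches) == 1:
        return data.copy()
    sizes = batch.value_counts()
    small = [b for b in batches if sizes[b] < 2]
    if small:
        raise BatchCorrectionError(
            f"plates with fewer than 2 samples cannot be corrected: {small}"
        )
    X = data.to_numpy(dtype=float)  # n x m
    n, m = X.shape
    batch_design = pd.get_dummies(batch, dtype=float)[batches].to_numpy()
    n_batch = len(batches)
    design = batch_design
    if covariates is not None and covariates.shape[1] > 0:
        design = np.hstack([batch_design, covariates.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)  # p x m
    n_i = batch_design.sum(axis=0)
    grand_mean = (n_i / n) @ beta[:n_batch]
    var_pooled = ((X - design @ beta) ** 2).sum(axis=0) / n
    if np.any(var_pooled <= 0):
        raise BatchCorrectionError(
            "zero pooled variance for at least one metabolite"
        )
    stand_mean = np.tile(grand_mean, (n, 1))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + design[:, n_batch:] @ beta[n_batch:]
    Z = (X - stand_mean) / np.sqrt(var_pooled)[None, :]

    adjusted = Z.copy()
    for b_idx, b in enumerate(batches):
        rows = batch_design[:, b_idx] == 1.0
        zb = Z[rows]
        g_hat = zb.mean(axis=0)
        d_hat = zb.var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        d_mean, d_var = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2.0 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var
        g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        adjusted[rows] = (zb - g_star[None, :]) / np.sqrt(d_star)[None, :]

    out = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    return pd.DataFrame(out, index=data.index, columns=data.columns)


# ----------------------------------------------------------------------
# normalized panel
# ----------------------------------------------------------------------

@dataclass
class NormalizedPanel:
    """Fully preprocessed panel ready for statistics and classification.

    ``imputed`` holds complete concentrations (μmol) over the tier-1 set;
    ``log2bc`` the log2 batch-corrected matrix; ``permille`` the per-sample
    permille shares over the quantitative tier; ``provenance`` records per
    cell whether the value was observed, zero-imputed or kNN-imputed.
    """

    imputed: pd.DataFrame
    log2bc: pd.DataFrame
    permille: pd.DataFrame
    provenance: pd.DataFrame
    samples: pd.DataFrame
    metabolites: pd.DataFrame
    group_order: tuple[str, ...]
    retained_all: list[str] = field(default_factory=list)
    retained_quant: list[str] = field(default_factory=list)
    knn_log: pd.DataFrame | None = None

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]


def log2_and_batch_correct(
    panel: MetabolitePanel,
    retained: list[str] | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Log2-transform the imputed concentrations and remove plate effects.

    Plates are treated as batches; per-plate location/scale effects are
    estimated per metabolite, shrunk via parametric empirical Bayes across
    metabolites, and removed.  When ``config.protect_group`` is set the group
    label enters the location model as a preserved covariate.
    """
    config = config or AnalysisConfig()
    cols = list(retained) if retained is not None else list(panel.concentrations.columns)
    conc = panel.concentrations[cols]
    if conc.isna().any().any():
        raise BatchCorrectionError(
            "panel must be complete (imputed) before batch correction"
        )
    if (conc <= 0).any().any():
        raise BatchCorrectionError("non-positive concentration before log2")
    log2 = np.log2(conc)
    covs = None
    if config.protect_group:
        covs = pd.get_dummies(panel.samples["group"], drop_first=True, dtype=float)
    return combat(log2, panel.samples["plate"], covs)


def normalize_permille(
    imputed: pd.DataFrame, quant_ids: list[str] | None = None
) -> pd.DataFrame:
    """Express each compound as permille (‰) of the sample's total
    concentration over the quantitative tier; rows sum to 1000."""
    cols = list(quant_ids) if quant_ids is not None else list(imputed.columns)
    block = imputed[cols]
    if block.isna().any().any():
        raise NormalizationError("permille normalization requires a complete matrix")
    totals = block.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        raise NormalizationError(
            f"zero total concentration for sample {totals.index[zero][0]!r}"
        )
    return block.div(totals, axis=0) * 1000.0


def aggregate_classes(
    normalized: NormalizedPanel | None = None,
    *,
    imputed: pd.DataFrame | None = None,
    classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample aggregated concentration of each lipid class, plus each
    class's percentage contribution to the sample total."""
    if normalized is not None:
        imputed = normalized.imputed
        classes = normalized.metabolites.loc[imputed.columns, "class"]
    if imputed is None or classes is None:
        raise ValueError("provide either a NormalizedPanel or imputed+classes")
    totals = imputed.T.groupby(classes.to_numpy()).sum().T
    share = totals.div(totals.sum(axis=1), axis=0) * 100.0
    share.columns = [f"{c}_pct" for c in share.columns]
    return pd.concat([totals, share], axis=1)


def preprocess_panel(
    panel: MetabolitePanel,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> tuple[MissingnessPolicyResult, NormalizedPanel]:
    """Run the full chain: policy → dual imputation → log2 + batch
    correction → permille normalization.  Returns the policy result and the
    normalized panel."""
    config = config or AnalysisConfig()
    if seed is None:
        seed = config.seed
    policy = apply_missingness_policy(panel, config)
    sub = panel.subset_metabolites(policy.retained_all)
    sub = impute_below_loq(sub, policy.retained_all, seed=seed, config=config)
    sub, knn_log = impute_knn(sub, policy.retained_all, k=config.knn_k, config=config)
    log2bc = log2_and_batch_correct(sub, policy.retained_all, config)
    permille = normalize_permille(sub.concentrations, policy.retained_quant)
    return policy, NormalizedPanel(
        imputed=sub.concentrations.copy(),
        log2bc=log2bc,
        permille=permille,
        provenance=panel.codes[policy.retained_all].copy(),
        samples=panel.samples.copy(),
        metabolites=panel.metabolites.copy(),
        group_order=panel.group_order,
        retained_all=policy.retained_all,
        retained_quant=policy.retained_quant,
        knn_log=knn_log,
    )
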