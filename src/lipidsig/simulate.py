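"""Synthetic panel generator.

Emulates the statistical structure of a three-group targeted-lipidomics
screening cohort: log-normal per-compound concentrations with per-class
levels, additive per-plate (batch) shifts on the log2 scale, strong
inter-individual heterogeneity shared across compounds, mechanistic below-LOQ
truncation plus explicit "zero"-type missingness, independent
internal-standard failures, and multiplicative planted group effects.

All randomness flows from ``config.seed`` through a single
``numpy.random.Generator`` with a fixed draw order, so a given configuration
produces a bit-identical panel on every run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .errors import ConfigurationError
from .panel import MetabolitePanel, MissingCode

# typical acyl-carbon baseline used to build readable compound names per class
_NAME_BASE = {
    "AC": 2, "LPC": 14, "PC": 30, "PC-O": 30, "SM": 30,
    "Cer": 34, "DG": 30, "TG": 44, "CE": 14, "HEX": 0,
}


def _allocate_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder allocation of metabolite counts to lipid classes."""
    classes = list(config.class_proportions)
    raw = np.array([config.class_proportions[c] for c in classes]) * config.n_metabolites
    counts = np.floor(raw).astype(int)
    rema = raw - counts
    for i in np.argsort(-rema)[: config.n_metabolites - counts.sum()]:
        counts[i] += 1
    return dict(zip(classes, counts))


def metabolite_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Deterministic metabolite identifiers and their lipid classes.

    Names follow the field's shorthand, e.g. ``PC(38:6)`` or ``Cer(42:1)``;
    they are opaque identifiers here — acyl-chain composition is never parsed.
    """
    counts = _allocate_counts(config)
    ids, classes = [], []
    for cls, n in counts.items():
        base = _NAME_BASE.get(cls, 30)
        for k in range(n):
            if cls == "HEX":
                ids.append(f"HEX{k + 1}" if n > 1 else "HEX")
            else:
                ids.append(f"{cls}({base + 2 * (k // 8)}:{k % 8})")
            classes.append(cls)
    return ids, classes


def _plate_assignment(config: SimulationConfig) -> np.ndarray:
    """Plate index per sample: enrolment order interleaves groups, plates
    are filled in contiguous blocks so each plate stays group-balanced."""
    n_total = config.n_per_group * len(config.groups)
    block = int(np.ceil(n_total / config.n_plates))
    return np.arange(n_total) // block


def generate_panel(config: SimulationConfig) -> MetabolitePanel:
    """Draw one synthetic panel under ``config``.

    Concentrations follow ``log2 x = class mean + compound offset + plate
    shift + sample heterogeneity + residual``; planted effects multiply the
    affected group's concentrations before missingness is injected, so planted
    fold-changes act on complete data.  Cells falling below the plate LOQ (the
    ``loq_quantile`` of the compound's generating distribution) or selected at
    the explicit zero rate are coded ``BELOW_LOQ``; an independent fraction is
    coded ``IS_FAILURE``.
    """
    rng = np.random.default_rng(config.seed)
    ids, classes = metabolite_ids(config)
    m = len(ids)
    groups = np.repeat(config.groups, config.n_per_group)
    # enrolment order: one sample of each group in turn
    order = np.arange(len(groups)).reshape(len(config.groups), config.n_per_group).T.ravel()
    groups = groups[order]
    n = len(groups)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    plates = _plate_assignment(config)
    plate_labels = np.array([f"P{p + 1}" for p in plates])

    known = set(ids)
    for eff in config.effects:
        if eff.metabolite not in known:
            raise ConfigurationError(
                f"effects: metabolite {eff.metabolite!r} does not exist in the "
                f"generated panel"
            )

    class_mean = np.array([config.class_log2_mean[c] for c in classes])
    offsets = rng.normal(0.0, config.class_log2_sd, size=m)
    shifts = rng.normal(0.0, config.plate_shift_sd, size=(config.n_plates, m))
    hetero = rng.normal(0.0, config.heterogeneity_sd, size=n)
    resid = rng.normal(0.0, config.residual_log2_sd, size=(n, m))
    rho = config.within_class_correlation
    if rho > 0:
        class_arr = np.asarray(classes)
        factor = rng.normal(0.0, config.residual_log2_sd,
                            size=(n, len(set(classes))))
        cls_index = {c: i for i, c in enumerate(dict.fromkeys(classes))}
        fcols = factor[:, [cls_index[c] for c in class_arr]]
        resid = np.sqrt(rho) * fcols + np.sqrt(1.0 - rho) * resid

    log2x = (class_mean + offsets)[None, :] + shifts[plates, :] + hetero[:, None] + resid
    conc = np.exp2(log2x)

    group_arr = np.asarray(groups)
    for eff in config.effects:
        j = ids.index(eff.metabolite)
        conc[group_arr == eff.group, j] *= eff.fold_change

    # per-plate LOQ at a low quantile of the generating distribution
    sd_total = float(np.hypot(config.heterogeneity_sd, config.residual_log2_sd))
    z_q = stats.norm.ppf(config.loq_quantile)
    loq_log2 = (class_mean + offsets)[None, :] + shifts + z_q * sd_total
    loq = np.exp2(loq_log2)  # (n_plates, m)

    # missingness: mechanistic truncation + explicit per-compound zero rate
    n_poor = int(round(config.poorly_detected_fraction * m))
    poor = np.zeros(m, dtype=bool)
    poor[rng.choice(m, size=n_poor, replace=False)] = True
    lo, hi = config.poorly_detected_zero_range
    zero_rate = np.full(m, config.zero_missing_rate)
    zero_rate[poor] = rng.uniform(lo, hi, size=n_poor)

    codes = np.zeros((n, m), dtype=np.int8)
    below = conc < loq[plates, :]
    below |= rng.random(size=(n, m)) < zero_rate[None, :]
    codes[below] = int(MissingCode.BELOW_LOQ)
    is_fail = rng.random(size=(n, m)) < config.is_missing_rate
    is_fail &= codes == int(MissingCode.OBSERVED)
    codes[is_fail] = int(MissingCode.IS_FAILURE)
    conc = conc.copy()
    conc[codes != int(MissingCode.OBSERVED)] = np.nan

    samples = pd.DataFrame(
        {"group": group_arr, "plate": plate_labels}, index=pd.Index(sample_ids, name="sample_id")
    )
    metabolites = pd.DataFrame(
        {"class": classes}, index=pd.Index(ids, name="metabolite_id")
    )
    for p in range(config.n_plates):
        metabolites[f"LOQ_P{p + 1}"] = loq[p]

    return MetabolitePanel(
        concentrations=pd.DataFrame(conc, index=samples.index, columns=metabolites.index),
        codes=pd.DataFrame(codes, index=samples.index, columns=metabolites.index),
        samples=samples,
        metabolites=metabolites,
        group_order=tuple(config.groups),
    )


def null_panel(config: SimulationConfig) -> MetabolitePanel:
    """A panel generated with the effects list emptied: every compound's group
    distributions share one generating law, so group labels carry no signal."""
    return generate_panel(config.replace(effects=()))
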