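"""Configuration objects for synthetic panel generation and for the analysis chain.

Two dataclasses hold every numeric policy constant of the pipeline:

* :class:`SimulationConfig` — the study-design constants of the emulated
  three-group screening cohort (81 samples per group, 96-well plates as
  batches, per-class log-normal concentration levels, two missingness
  mechanisms) plus the planted group effects used by oracle tests.
* :class:`AnalysisConfig` — the analysis constants: the 50%/10% missingness
  ceilings, kNN neighbourhood size, the 8-fold outer CV with 8 test samples
  per group, the 100-repeat 70/30 multiple random cross-validation, the
  forward-selection stop rule ``ΔBIC ≤ 2``, and the 5% significance level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError

#: Lipid classes of a Biocrates-style targeted panel: acylcarnitines,
#: lyso-/diacyl-/ether-phosphatidylcholines, sphingomyelins, ceramides,
#: di-/triglycerides, cholesteryl esters and hexose.
LIPID_CLASSES = ("AC", "LPC", "PC", "PC-O", "SM", "Cer", "DG", "TG", "CE", "HEX")

#: Default share of panel compounds per lipid class (approximate composition
#: of the quantifiable part of a 400-compound targeted lipidomics assay).
DEFAULT_CLASS_PROPORTIONS: Mapping[str, float] = {
    "AC": 0.10,
    "LPC": 0.08,
    "PC": 0.38,
    "PC-O": 0.10,
    "SM": 0.07,
    "Cer": 0.05,
    "DG": 0.04,
    "TG": 0.13,
    "CE": 0.04,
    "HEX": 0.01,
}

#: Default per-class mean log2 concentration (μmol).  Chosen so that
#: cholesteryl esters dominate the aggregated mass (about two thirds of the
#: total) and choline-containing phospholipids contribute about a quarter,
#: mimicking the composition of an LDL-depleted serum sEV fraction.
DEFAULT_CLASS_LOG2_MEAN: Mapping[str, float] = {
    "AC": -4.0,
    "LPC": -1.5,
    "PC": -1.0,
    "PC-O": -2.5,
    "SM": -1.5,
    "Cer": -3.5,
    "DG": -2.5,
    "TG": 0.0,
    "CE": 4.2,
    "HEX": 1.0,
}


def _check_rate(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative group effect planted on one compound.

    Parameters
    ----------
    metabolite : str
        Identifier of the affected compound (must exist in the panel).
    group : str
        Group label whose concentrations are multiplied.
    fold_change : float
        Multiplicative factor on the concentration scale; e.g. ``1.326``
        reproduces a ceramide-like lung-cancer effect of realistic magnitude.
    """

    metabolite: str
    group: str
    fold_change: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ConfigurationError(
                f"fold_change must be > 0, got {self.fold_change!r}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants for the synthetic panel generator.

    Concentrations are log-normal per compound:
    ``log2 x = class mean + compound offset + plate shift + sample
    heterogeneity + residual noise``, with planted effects applied
    multiplicatively on the concentration scale before missingness is
    injected.
    """

    n_per_group: int = 81
    groups: tuple[str, ...] = ("HC", "LN", "LC")
    n_metabolites: int = 352
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    n_plates: int = 3
    #: sd of additive per-plate, per-metabolite shifts on the log2 scale.
    plate_shift_sd: float = 0.30
    #: per-class mean log2 concentration (μmol).
    class_log2_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_LOG2_MEAN)
    )
    #: sd of per-compound offsets around the class mean.
    class_log2_sd: float = 1.0
    #: per-cell residual sd on the log2 scale (~25% CV at 0.35).
    residual_log2_sd: float = 0.35
    #: per-sample log2 shift shared by all metabolites (inter-individual
    #: lipid-load heterogeneity; cancels under permille normalization).
    heterogeneity_sd: float = 0.30
    #: baseline probability that a cell is coded below-LOQ, on top of the
    #: mechanistic truncation at the plate LOQ.
    zero_missing_rate: float = 0.03
    #: probability that a cell is coded as an internal-standard failure.
    is_missing_rate: float = 0.02
    #: fraction of compounds that are poorly detected (high zero rates);
    #: the default reproduces a panel where roughly 151 of 352 compounds
    #: fail the quantitative 50%-zeros tier.
    poorly_detected_fraction: float = 151.0 / 352.0
    #: per-group below-LOQ rate range for poorly detected compounds.
    poorly_detected_zero_range: tuple[float, float] = (0.55, 0.95)
    #: quantile of a compound's generating distribution that defines the
    #: per-plate limit of quantitation.
    loq_quantile: float = 0.025
    #: optional equicorrelation of compound offsets within a lipid class.
    within_class_correlation: float = 0.0
    effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError(
                f"n_per_group must be >= 2, got {self.n_per_group!r}"
            )
        if len(self.groups) < 2:
            raise ConfigurationError("groups must contain at least two labels")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("groups must be distinct labels")
        if self.n_metabolites < 1:
            raise ConfigurationError(
                f"n_metabolites must be >= 1, got {self.n_metabolites!r}"
            )
        if self.n_plates < 1:
            raise ConfigurationError(f"n_plates must be >= 1, got {self.n_plates!r}")
        total = float(sum(self.class_proportions.values()))
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"class_proportions must sum to 1 (got {total:.6f})"
            )
        unknown = set(self.class_proportions) - set(LIPID_CLASSES)
        if unknown:
            raise ConfigurationError(
                f"class_proportions contains unknown classes: {sorted(unknown)}"
            )
        for name in ("zero_missing_rate", "is_missing_rate",
                     "poorly_detected_fraction", "loq_quantile"):
            _check_rate(name, getattr(self, name))
        lo, hi = self.poorly_detected_zero_range
        _check_rate("poorly_detected_zero_range[0]", lo)
        _check_rate("poorly_detected_zero_range[1]", hi)
        if lo > hi:
            raise ConfigurationError(
                "poorly_detected_zero_range must be ordered (low, high)"
            )
        if not (0.0 <= self.within_class_correlation < 1.0):
            raise ConfigurationError(
                "within_class_correlation must lie in [0, 1)"
            )
        for eff in self.effects:
            if eff.group not in self.groups:
                raise ConfigurationError(
                    f"effects: group {eff.group!r} not among declared groups"
                )

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimulationConfig":
        data = dict(mapping)
        if "effects" in data:
            data["effects"] = tuple(
                eff if isinstance(eff, PlantedEffect) else PlantedEffect(**eff)
                for eff in data["effects"]
            )
        if "groups" in data:
            data["groups"] = tuple(data["groups"])
        if "poorly_detected_zero_range" in data:
            data["poorly_detected_zero_range"] = tuple(
                data["poorly_detected_zero_range"]
            )
        return cls(**data)


@dataclass(frozen=True)
class AnalysisConfig:
    """Numeric policy constants of the analysis chain."""

    #: tier-1 ceiling on per-group below-LOQ fraction ("50% allowed").
    zero_missing_ceiling: float = 0.50
    #: tier-1 ceiling on per-group internal-standard-failure fraction.
    is_missing_ceiling: float = 0.10
    #: tier-2 (quantitative) ceiling: strict "< 50% zeros in each group".
    quantitative_zero_ceiling: float = 0.50
    knn_k: int = 3
    #: minimum shared observed metabolites for a correlation distance.
    min_shared_metabolites: int = 10
    #: truncated-normal parameterization for below-LOQ imputation:
    #: untruncated mean = trunc_mean_frac * LOQ, sd = trunc_sd_frac * LOQ.
    trunc_mean_frac: float = 0.5
    trunc_sd_frac: float = 0.25
    #: preserve group labels as a covariate during batch correction.
    protect_group: bool = True
    mrcv_repeats: int = 100
    outer_folds: int = 8
    test_per_group: int = 8
    teach_fraction: float = 0.70
    delta_bic_stop: float = 2.0
    ci_level: float = 0.95
    alpha: float = 0.05
    #: ridge penalty on slopes stabilising separable logistic fits
    #: (excluded from the BIC parameter count).
    ridge: float = 1e-6
    #: optional cap on forward-selection candidates; when set, candidates
    #: are pre-screened by omnibus rank test within the training samples.
    max_candidate_features: int | None = None
    #: effect-size denominator for the standardized Conover r:
    #: "pair" -> sqrt(n_i + n_j); "total" -> sqrt(n).
    r_denominator: str = "pair"
    #: three-class AUC definition: macro one-vs-rest ("ovr_macro") or
    #: Hand-Till ("hand_till").
    multiclass_auc: str = "ovr_macro"
    #: classifier feature scale: "permille" or "log2" (batch-corrected).
    feature_scale: str = "permille"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("zero_missing_ceiling", "is_missing_ceiling",
                     "quantitative_zero_ceiling", "teach_fraction",
                     "ci_level", "alpha"):
            _check_rate(name, getattr(self, name))
        if self.knn_k < 1:
            raise ConfigurationError(f"knn_k must be >= 1, got {self.knn_k!r}")
        if self.outer_folds < 2:
            raise ConfigurationError(
                f"outer_folds must be >= 2, got {self.outer_folds!r}"
            )
        if not self.delta_bic_stop > 0:
            raise ConfigurationError(
                f"delta_bic_stop must be > 0, got {self.delta_bic_stop!r}"
            )
        if self.mrcv_repeats < 1:
            raise ConfigurationError(
                f"mrcv_repeats must be >= 1, got {self.mrcv_repeats!r}"
            )
        if self.test_per_group < 1:
            raise ConfigurationError(
                f"test_per_group must be >= 1, got {self.test_per_group!r}"
            )
        if self.r_denominator not in ("pair", "total"):
            raise ConfigurationError(
                f"r_denominator must be 'pair' or 'total', got {self.r_denominator!r}"
            )
        if self.multiclass_auc not in ("ovr_macro", "hand_till"):
            raise ConfigurationError(
                f"multiclass_auc must be 'ovr_macro' or 'hand_till', "
                f"got {self.multiclass_auc!r}"
            )
        if self.feature_scale not in ("permille", "log2"):
            raise ConfigurationError(
                f"feature_scale must be 'permille' or 'log2', "
                f"got {self.feature_scale!r}"
            )
        if not self.ridge >= 0:
            raise ConfigurationError(f"ridge must be >= 0, got {self.ridge!r}")

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        return cls(**dict(mapping))
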