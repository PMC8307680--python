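"""The central panel container: a samples x metabolites concentration matrix
with a three-state missingness code matrix and sample/metabolite metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import LIPID_CLASSES
from .errors import PanelFormatError


class MissingCode(enum.IntEnum):
    """Per-cell measurement status.

    ``BELOW_LOQ`` marks a "zero"-type value below the plate-specific limit of
    quantitation; ``IS_FAILURE`` marks a measurement lost to an
    internal-standard error.  The two kinds are handled by different
    imputation schemes downstream.
    """

    OBSERVED = 0
    BELOW_LOQ = 1
    IS_FAILURE = 2


@dataclass
class MetabolitePanel:
    """A validated samples x metabolites concentration panel (μmol).

    Attributes
    ----------
    concentrations : pandas.DataFrame
        Samples x metabolites, float; ``NaN`` wherever the code matrix is not
        ``OBSERVED``.
    codes : pandas.DataFrame
        Same shape, ``int8`` values from :class:`MissingCode`.
    samples : pandas.DataFrame
        Indexed by sample id, columns ``group`` and ``plate``.
    metabolites : pandas.DataFrame
        Indexed by metabolite id, column ``class`` plus one ``LOQ_<plate>``
        column per plate (μmol).
    group_order : tuple of str
        Declared ordered set of group labels.
    """

    concentrations: pd.DataFrame
    codes: pd.DataFrame
    samples: pd.DataFrame
    metabolites: pd.DataFrame
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        conc, codes = self.concentrations, self.codes
        if conc.shape != codes.shape:
            raise PanelFormatError(
                f"concentration matrix {conc.shape} does not match code "
                f"matrix {codes.shape}"
            )
        if not conc.index.equals(codes.index) or not conc.columns.equals(codes.columns):
            raise PanelFormatError("concentration and code matrices are misaligned")
        if not conc.index.equals(self.samples.index):
            raise PanelFormatError(
                "matrix rows do not match the sample table "
                f"({len(conc.index)} rows vs {len(self.samples)} samples)"
            )
        if not conc.columns.equals(self.metabolites.index):
            raise PanelFormatError(
                "matrix columns do not match the metabolite table "
                f"({len(conc.columns)} columns vs {len(self.metabolites)} metabolites)"
            )
        for col in ("group", "plate"):
            if col not in self.samples.columns:
                raise PanelFormatError(f"sample table lacks a {col!r} column")
        if "class" not in self.metabolites.columns:
            raise PanelFormatError("metabolite table lacks a 'class' column")
        bad_groups = set(self.samples["group"]) - set(self.group_order)
        if bad_groups:
            offender = self.samples.index[
                self.samples["group"].isin(bad_groups)
            ][0]
            raise PanelFormatError(
                f"sample {offender!r} carries undeclared group label "
                f"{self.samples.loc[offender, 'group']!r}"
            )
        bad_classes = set(self.metabolites["class"]) - set(LIPID_CLASSES)
        if bad_classes:
            raise PanelFormatError(
                f"unknown lipid classes in metabolite table: {sorted(bad_classes)}"
            )
        loq_cols = {f"LOQ_{p}" for p in self.samples["plate"].unique()}
        missing_loq = loq_cols - set(self.metabolites.columns)
        if missing_loq:
            offender = self.samples.index[
                self.samples["plate"].map(lambda p: f"LOQ_{p}" in missing_loq)
            ][0]
            raise PanelFormatError(
                f"sample {offender!r} sits on a plate with no LOQ column "
                f"({sorted(missing_loq)})"
            )
        code_values = codes.to_numpy()
        valid = np.isin(code_values, [int(c) for c in MissingCode])
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise PanelFormatError(
                f"invalid missingness code {code_values[i, j]!r} at "
                f"sample {conc.index[i]!r}, metabolite {conc.columns[j]!r}"
            )
        values = conc.to_numpy(dtype=float)
        observed = code_values == int(MissingCode.OBSERVED)
        bad = observed & ~(np.isfinite(values) & (values >= 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelFormatError(
                f"observed concentration at sample {conc.index[i]!r}, "
                f"metabolite {conc.columns[j]!r} is not finite and >= 0: "
                f"{values[i, j]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def plates(self) -> tuple:
        return tuple(pd.unique(self.samples["plate"]))

    def loq(self, metabolite: str, plate) -> float:
        """Plate-specific limit of quantitation for a metabolite (μmol)."""
        col = f"LOQ_{plate}"
        if col not in self.metabolites.columns:
            raise PanelFormatError(f"no LOQ column for plate {plate!r}")
        return float(self.metabolites.loc[metabolite, col])

    def loq_matrix(self) -> pd.DataFrame:
        """Per-cell LOQ matrix aligned with the concentration matrix."""
        cols = [f"LOQ_{p}" for p in self.samples["plate"]]
        loq = self.metabolites[cols].to_numpy(dtype=float).T
        return pd.DataFrame(
            loq, index=self.concentrations.index, columns=self.concentrations.columns
        )

    def missing_fractions(self) -> pd.DataFrame:
        """Per group x metabolite fraction of each missingness type."""
        rows = []
        for group, idx in self.samples.groupby("group", sort=False).groups.items():
            sub = self.codes.loc[idx].to_numpy()
            rows.append(
                pd.DataFrame(
                    {
                        "group": group,
                        "metabolite": self.concentrations.columns,
                        "frac_below_loq": (sub == int(MissingCode.BELOW_LOQ)).mean(axis=0),
                        "frac_is_failure": (sub == int(MissingCode.IS_FAILURE)).mean(axis=0),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def subset_metabolites(self, ids) -> "MetabolitePanel":
        ids = list(ids)
        return MetabolitePanel(
            concentrations=self.concentrations[ids].copy(),
            codes=self.codes[ids].copy(),
            samples=self.samples.copy(),
            metabolites=self.metabolites.loc[ids].copy(),
            group_order=self.group_order,
        )

    def copy(self) -> "MetabolitePanel":
        return MetabolitePanel(
            concentrations=self.concentrations.copy(),
            codes=self.codes.copy(),
            samples=self.samples.copy(),
            metabolites=self.metabolites.copy(),
            group_order=self.group_order,
        )

    def equals(self, other: "MetabolitePanel") -> bool:
        return (
            self.group_order == other.group_order
            and self.concentrations.equals(other.concentrations)
            and self.codes.equals(other.codes)
            and self.samples.equals(other.samples)
            and self.metabolites.equals(other.metabolites)
        )
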