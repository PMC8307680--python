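"""Panel exchange format and result-table writing.

The on-disk dialect is a directory of three tab-separated UTF-8 files:

* ``concentrations.tsv`` — wide matrix, one row per sample, one column per
  metabolite; missing cells carry the sentinels ``<LOQ`` (below the limit of
  quantitation) or ``NA_IS`` (internal-standard failure).
* ``samples.tsv`` — ``sample_id``, ``group``, ``plate``.
* ``metabolites.tsv`` — ``metabolite_id``, ``class``, then one
  ``LOQ_<plate>`` column per plate (μmol).

``read_panel(write_panel(p)) == p`` bit-exactly, including the missingness
code matrix and the LOQ table.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PanelFormatError
from .panel import MetabolitePanel, MissingCode

SENTINELS = {"<LOQ": MissingCode.BELOW_LOQ, "NA_IS": MissingCode.IS_FAILURE}
_CODE_TO_SENTINEL = {int(v): k for k, v in SENTINELS.items()}

_GROUP_FILE = "groups.txt"


def write_panel(panel: MetabolitePanel, path: os.PathLike | str) -> Path:
    """Write ``panel`` to directory ``path`` in the TSV dialect; returns the path."""
    if panel.n_metabolites == 0:
        raise PanelFormatError("refusing to write a panel with no metabolites")
    if panel.n_samples == 0:
        raise PanelFormatError("refusing to write a panel with no samples")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    cells = panel.concentrations.copy().astype(object)
    codes = panel.codes.to_numpy()
    arr = cells.to_numpy()
    conc = panel.concentrations.to_numpy()
    out = np.empty(arr.shape, dtype=object)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            code = int(codes[i, j])
            if code == int(MissingCode.OBSERVED):
                out[i, j] = repr(float(conc[i, j]))
            else:
                out[i, j] = _CODE_TO_SENTINEL[code]
    text = pd.DataFrame(out, index=cells.index, columns=cells.columns)
    text.to_csv(path / "concentrations.tsv", sep="\t", index_label="sample_id")
    panel.samples.to_csv(path / "samples.tsv", sep="\t", index_label="sample_id")
    panel.metabolites.to_csv(
        path / "metabolites.tsv", sep="\t", index_label="metabolite_id",
        float_format="%.17g",
    )
    (path / _GROUP_FILE).write_text("\n".join(panel.group_order) + "\n", encoding="utf-8")
    return path


def read_panel(path: os.PathLike | str) -> MetabolitePanel:
    """Read a panel directory written by :func:`write_panel` and validate it."""
    path = Path(path)
    for fname in ("concentrations.tsv", "samples.tsv", "metabolites.tsv", _GROUP_FILE):
        if not (path / fname).exists():
            raise PanelFormatError(f"panel directory {path} lacks {fname}")
    text = pd.read_csv(
        path / "concentrations.tsv", sep="\t", index_col="sample_id", dtype=str
    )
    samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col="sample_id")
    metabolites = pd.read_csv(
        path / "metabolites.tsv", sep="\t", index_col="metabolite_id",
        float_precision="round_trip",
    )
    group_order = tuple(
        line for line in (path / _GROUP_FILE).read_text(encoding="utf-8").splitlines()
        if line
    )

    conc = np.full(text.shape, np.nan)
    codes = np.zeros(text.shape, dtype=np.int8)
    arr = text.to_numpy()
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            cell = arr[i, j]
            if cell in SENTINELS:
                codes[i, j] = int(SENTINELS[cell])
                continue
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise PanelFormatError(
                    f"malformed numeric cell {cell!r} at sample "
                    f"{text.index[i]!r}, metabolite {text.columns[j]!r}"
                ) from None
            if not np.isfinite(value) or value < 0:
                raise PanelFormatError(
                    f"negative or non-finite concentration {value!r} at sample "
                    f"{text.index[i]!r}, metabolite {text.columns[j]!r}"
                )
            conc[i, j] = value

    return MetabolitePanel(
        concentrations=pd.DataFrame(conc, index=text.index, columns=text.columns),
        codes=pd.DataFrame(codes, index=text.index, columns=text.columns),
        samples=samples,
        metabolites=metabolites,
        group_order=group_order,
    )


def write_table(
    table: pd.DataFrame,
    path: os.PathLike | str,
    *,
    config=None,
    seed: int | None = None,
    index: bool = False,
) -> Path:
    """Write a result table as TSV with a ``#``-comment header recording the
    analysis configuration and seed, so every output is self-describing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(f"# config: {config!r}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        table.to_csv(fh, sep="\t", index=index)
    return path
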