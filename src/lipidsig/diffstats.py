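"""Differential-abundance statistics for three-group panels.

The screen is rank-based throughout: a tie-corrected Kruskal-Wallis omnibus
test per compound (with the eta-squared effect size
``η² = (H - k + 1)/(n - k)``, clipped at 0), followed by Conover-Iman
pairwise post hoc tests using the pooled tie-corrected rank variance and
t-distributed statistics, the standardized effect ``r = |t| / sqrt(n_i +
n_j)``, and median-based fold-changes.  Benjamini-Hochberg adjustment is
applied separately within each family (omnibus; each group pair; the
presence/absence family).  Compounds excluded from quantitation are compared
between groups by a chi-squared test on their absent/present status.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import LipidsigError
from .panel import MetabolitePanel, MissingCode


# ----------------------------------------------------------------------
# building blocks
# ----------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise LipidsigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def kruskal_wallis_screen(values: pd.DataFrame, groups) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H, p and eta-squared per metabolite.

    A compound constant across all samples is reported as ``H = 0, p = 1``
    with ``flagged_constant = True`` rather than raising.
    """
    groups = np.asarray(groups, dtype=object)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise LipidsigError("need at least two groups")
    masks = [groups == g for g in labels]
    for g, m in zip(labels, masks):
        if m.sum() < 2:
            raise LipidsigError(f"group {g!r} has fewer than 2 samples")
    n = len(groups)
    k = len(labels)
    rows = []
    for met in values.columns:
        x = values[met].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append({"metabolite": met, "H": 0.0, "p": 1.0,
                         "eta_sq": 0.0, "flagged_constant": True})
            continue
        H, p = stats.kruskal(*[x[m] for m in masks])
        eta = max(0.0, min(1.0, (H - k + 1) / (n - k)))
        rows.append({"metabolite": met, "H": float(H), "p": float(p),
                     "eta_sq": eta, "flagged_constant": False})
    out = pd.DataFrame(rows).set_index("metabolite")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def conover_posthoc(
    values: pd.DataFrame,
    groups,
    pairs: list[tuple[str, str]] | None = None,
    r_denominator: str = "pair",
) -> pd.DataFrame:
    """Conover-Iman pairwise post hoc tests per metabolite.

    Uses the pooled tie-corrected rank variance
    ``S² = (Σ R² - n (n+1)²/4) / (n - 1)`` and the finite-sample correction
    ``(n - 1 - H)/(n - k)``; two-sided p from Student's t with ``n - k``
    degrees of freedom.  The standardized effect size is
    ``r = |t| / sqrt(n_i + n_j)`` (or ``|t| / sqrt(n)`` when
    ``r_denominator="total"``).
    """
    groups = np.asarray(groups, dtype=object)
    labels = list(pd.unique(groups))
    if pairs is None:
        pairs = list(combinations(labels, 2))
    for a, b in pairs:
        for g in (a, b):
            if (groups == g).sum() == 0:
                raise LipidsigError(f"pair ({a!r}, {b!r}): group {g!r} is empty")
    n = len(groups)
    k = len(labels)
    masks = {g: groups == g for g in labels}
    sizes = {g: int(m.sum()) for g, m in masks.items()}
    rows = []
    for met in values.columns:
        x = values[met].to_numpy(dtype=float)
        ranks = stats.rankdata(x)
        if np.all(x == x[0]):
            for a, b in pairs:
                rows.append({"metabolite": met, "pair": f"{a}-{b}",
                             "t": 0.0, "p": 1.0, "r": 0.0})
            continue
        H, _ = stats.kruskal(*[x[masks[g]] for g in labels])
        S2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
        correction = (n - 1.0 - H) / (n - k)
        for a, b in pairs:
            ra, rb = ranks[masks[a]].mean(), ranks[masks[b]].mean()
            denom = np.sqrt(S2 * correction * (1.0 / sizes[a] + 1.0 / sizes[b]))
            t = (ra - rb) / denom if denom > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), df=n - k) if denom > 0 else 1.0
            n_eff = sizes[a] + sizes[b] if r_denominator == "pair" else n
            rows.append({"metabolite": met, "pair": f"{a}-{b}",
                         "t": float(t), "p": float(min(p, 1.0)),
                         "r": float(abs(t) / np.sqrt(n_eff))})
    out = pd.DataFrame(rows)
    # BH within each pair family across metabolites
    out["q"] = np.nan
    for pair_name, idx in out.groupby("pair").groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    return out


def fold_change_median(
    values: pd.DataFrame, groups, pair: tuple[str, str]
) -> pd.Series:
    """Median-based fold-change ``median(numerator)/median(denominator)``
    per metabolite; a zero denominator median yields NaN (flagged)."""
    groups = np.asarray(groups, dtype=object)
    num, den = pair
    mask_n, mask_d = groups == num, groups == den
    if mask_n.sum() == 0 or mask_d.sum() == 0:
        raise LipidsigError(f"pair {pair!r}: empty group")
    med_n = values.loc[mask_n].median(axis=0)
    med_d = values.loc[mask_d].median(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = med_n / med_d
    fc[med_d == 0] = np.nan
    fc.name = f"fc_{num}/{den}"
    return fc


def presence_chi2(
    panel: MetabolitePanel, excluded_ids: list[str]
) -> pd.DataFrame:
    """Chi-squared independence test of absent/present status by group for
    compounds excluded from quantitation.

    "Present" means the cell was observed (not below-LOQ, not an IS
    failure).  Degenerate tables (all present or all absent) get ``p = 1``
    and are flagged; tables with expected counts < 5 in more than 20% of
    cells are flagged as low-count.
    """
    groups = panel.samples["group"].to_numpy(dtype=object)
    labels = list(panel.group_order)
    rows = []
    for met in excluded_ids:
        present = (
            panel.codes[met].to_numpy() == int(MissingCode.OBSERVED)
        )
        table = np.array(
            [[present[groups == g].sum(), (~present)[groups == g].sum()]
             for g in labels]
        )
        degenerate = table[:, 0].sum() == 0 or table[:, 1].sum() == 0
        if degenerate:
            rows.append({"metabolite": met, "chi2": 0.0, "p": 1.0,
                         "flagged_degenerate": True, "flagged_low_count": False,
                         **_presence_cols(labels, table)})
            continue
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        low = (expected < 5).mean() > 0.20
        rows.append({"metabolite": met, "chi2": float(chi2), "p": float(p),
                     "flagged_degenerate": False, "flagged_low_count": bool(low),
                     **_presence_cols(labels, table)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.set_index("metabolite")
    return out


def _presence_cols(labels, table):
    cols = {}
    for g, (pres, absent) in zip(labels, table):
        cols[f"present_{g}"] = int(pres)
        cols[f"absent_{g}"] = int(absent)
    return cols


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------

class DifferentialAbundance:
    """Differential-abundance model for a complete permille matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Samples x metabolites matrix on the scale to be tested (the pipeline
        uses permille shares; all rank statistics are invariant under any
        strictly monotone transform).
    groups : array-like
        Group label per sample.
    group_order : sequence of str, optional
        Declared ordered label set; pairwise comparisons use later-vs-earlier
        orientation for fold-changes (e.g. LC/HC).
    """

    def __init__(self, values: pd.DataFrame, groups, group_order=None,
                 config: AnalysisConfig | None = None):
        self.values = values
        self.groups = np.asarray(groups, dtype=object)
        if group_order is None:
            group_order = tuple(pd.unique(self.groups))
        self.group_order = tuple(group_order)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_normalized(cls, normalized, config: AnalysisConfig | None = None):
        return cls(
            normalized.permille,
            normalized.groups.to_numpy(),
            group_order=normalized.group_order,
            config=config,
        )

    def fit(self, pairs: list[tuple[str, str]] | None = None
            ) -> "DifferentialAbundanceResults":
        if pairs is None:
            pairs = list(combinations(self.group_order, 2))
        omnibus = kruskal_wallis_screen(self.values, self.groups)
        pairwise = conover_posthoc(
            self.values, self.groups, pairs,
            r_denominator=self.config.r_denominator,
        )
        # fold-changes oriented later-vs-earlier in the declared order
        fc_frames = []
        for a, b in pairs:
            num, den = (b, a)  # e.g. (HC, LC) pair -> LC/HC fold-change
            fc = fold_change_median(self.values, self.groups, (num, den))
            frame = fc.rename("fold_change").to_frame()
            frame["pair"] = f"{a}-{b}"
            frame["fc_orientation"] = f"{num}/{den}"
            fc_frames.append(frame.reset_index(names="metabolite"))
        fc_all = pd.concat(fc_frames, ignore_index=True)
        pairwise = pairwise.merge(fc_all, on=["metabolite", "pair"], how="left")
        # p-value-based rank within each pair and fold-change direction
        pairwise["rank"] = np.nan
        for (pair_name, up), idx in pairwise.groupby(
            ["pair", pairwise["fold_change"] > 1.0]
        ).groups.items():
            sub = pairwise.loc[idx].sort_values(
                ["p", "metabolite"], kind="stable"
            )
            pairwise.loc[sub.index, "rank"] = np.arange(1, len(sub) + 1)
        return DifferentialAbundanceResults(self, omnibus, pairwise)


@dataclass
class DifferentialAbundanceResults:
    """Fitted differential table: omnibus and pairwise statistics."""

    model: DifferentialAbundance
    omnibus: pd.DataFrame
    pairwise: pd.DataFrame

    def significant(self, alpha: float | None = None,
                    adjusted: bool = False) -> pd.DataFrame:
        """Pairwise rows passing the gatekept screen: the omnibus test and
        the pairwise test both below ``alpha`` (raw p by default; the
        BH-adjusted q when ``adjusted=True``)."""
        alpha = alpha if alpha is not None else self.model.config.alpha
        col = "q" if adjusted else "p"
        omni_pass = self.omnibus.index[self.omnibus[col] < alpha]
        sub = self.pairwise[self.pairwise["metabolite"].isin(omni_pass)]
        return sub[sub[col] < alpha].copy()

    def summary(self, top: int = 10) -> pd.DataFrame:
        """Top compounds by omnibus p with their pairwise statistics."""
        best = self.omnibus.nsmallest(top, "p")
        sub = self.pairwise[self.pairwise["metabolite"].isin(best.index)]
        merged = sub.merge(
            best[["H", "p", "q", "eta_sq"]].rename(
                columns={"p": "omnibus_p", "q": "omnibus_q"}
            ),
            left_on="metabolite", right_index=True,
        )
        return merged.sort_values(
            ["omnibus_p", "metabolite", "pair"], kind="stable"
        ).reset_index(drop=True)


def compare_compartments(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    top_n: int = 5,
    pair: str | None = None,
) -> pd.DataFrame:
    """Contrast the top differential compounds of one compartment (e.g. sEV)
    with their statistics in another (e.g. whole serum).

    Takes the ``top_n`` compounds by pairwise p in ``table_a``, split by
    fold-change direction (up / down), and reports each compound's p,
    p-based rank and fold-change in ``table_b``; compounds absent from
    ``table_b`` are marked ``not detected/quantitated``.
    """
    a, b = table_a, table_b
    if pair is not None:
        a = a[a["pair"] == pair]
        b = b[b["pair"] == pair]
    rows = []
    for direction, mask in (("up", a["fold_change"] > 1.0),
                            ("down", a["fold_change"] <= 1.0)):
        sub = a[mask].sort_values(["p", "metabolite"], kind="stable")
        if top_n > len(sub):
            import warnings

            warnings.warn(
                f"top_n={top_n} exceeds the {len(sub)} available "
                f"{direction}-regulated compounds; truncating", stacklevel=2
            )
        for _, row in sub.head(top_n).iterrows():
            match = b[b["metabolite"] == row["metabolite"]]
            entry = {
                "metabolite": row["metabolite"],
                "direction": direction,
                "p_a": row["p"],
                "rank_a": row["rank"],
                "fold_change_a": row["fold_change"],
            }
            if len(match) == 0:
                entry.update(
                    {"p_b": np.nan, "rank_b": np.nan, "fold_change_b": np.nan,
                     "status_b": "not detected/quantitated"}
                )
            else:
                mrow = match.iloc[0]
                entry.update(
                    {"p_b": mrow["p"], "rank_b": mrow["rank"],
                     "fold_change_b": mrow["fold_change"], "status_b": "quantitated"}
                )
            rows.append(entry)
    return pd.DataFrame(rows)
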