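"""Signature discovery by nested cross-validated forward-BIC selection.

The procedure mirrors common practice for small-cohort biomarker panels:

* an outer 8-fold cross-validation extracts 8 test samples per group at each
  fold (non-overlapping draws without replacement; with 81 samples per group
  17 per group are never tested but remain in every training set);
* on each fold's training remainder, a multiple random cross-validation
  (MRCV; 100 stratified 70/30 teaching/testing splits) runs greedy forward
  feature selection for a multinomial logistic model with the stop criterion
  ``ΔBIC ≤ 2`` on the teaching part;
* the MRCV model collection yields a feature ranking (selection frequency,
  then mean addition order); the elbow of the frequency curve — the largest
  consecutive drop — cuts the ranked list into the fold's signature;
* the fold model is refitted on the full training remainder with the elbow
  features and evaluated by maximum-a-posteriori classification (binary
  models instead use a Youden-J threshold chosen on the training ROC);
* fold metrics (accuracy, AUC, per-class sensitivity/specificity) are
  aggregated as means with t-based 95% confidence intervals, and a final
  model is built from the elbow of the pooled ranking over all folds.

Everything is a pure function of ``(data, config, seed)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import LipidsigError
from .mlogit import FitError, MultinomialLogit, SignatureModel


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------

def map_classify(model: SignatureModel, X: pd.DataFrame) -> np.ndarray:
    """Maximum-a-posteriori class labels; exact probability ties break
    deterministically toward the earlier class in the declared order."""
    proba = model.predict_proba(X)
    return np.asarray(model.classes, dtype=object)[proba.argmax(axis=1)]


def youden_threshold(scores, labels, positive) -> float:
    """Decision threshold maximizing Youden's ``J = sensitivity +
    specificity - 1`` over all cut-points of the training ROC.

    Candidate thresholds are midpoints between consecutive distinct scores
    (plus guards beyond the extremes); among tied maximizers the midpoint of
    the tied interval is returned.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=object) == positive
    if y.all() or not y.any():
        raise LipidsigError("Youden threshold needs both classes present")
    uniq = np.unique(scores)
    cuts = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos, n_neg = y.sum(), (~y).sum()
    js = np.array(
        [(scores[y] >= c).sum() / n_pos + (scores[~y] < c).sum() / n_neg - 1.0
         for c in cuts]
    )
    best = np.flatnonzero(np.isclose(js, js.max()))
    # tie rule: midpoint of the tied threshold interval
    return float((cuts[best[0]] + cuts[best[-1]]) / 2.0)


def _binary_auc(scores, y_true) -> float:
    """Trapezoidal ROC area via the rank (Mann-Whitney) formulation."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _hand_till_auc(proba, y, classes) -> float:
    """Hand-Till M: average of pairwise one-vs-one AUCs."""
    aucs = []
    y = np.asarray(y, dtype=object)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            mask = (y == a) | (y == b)
            if (y[mask] == a).sum() == 0 or (y[mask] == b).sum() == 0:
                continue
            a_ij = _binary_auc(proba[mask, classes.index(a)], y[mask] == a)
            a_ji = _binary_auc(proba[mask, classes.index(b)], y[mask] == b)
            aucs.append((a_ij + a_ji) / 2.0)
    return float(np.mean(aucs)) if aucs else np.nan


def evaluate(
    model: SignatureModel,
    X: pd.DataFrame,
    y,
    config: AnalysisConfig | None = None,
) -> dict:
    """Accuracy, AUC and per-class sensitivity/specificity of a fitted model.

    Accuracy uses MAP classification (or the model's Youden threshold for
    binary models).  Binary AUC is the trapezoidal ROC area; the three-class
    AUC is macro-averaged one-vs-rest by default (Hand-Till optional).  An
    evaluation set containing a single class gets ``auc = NaN`` (flagged).
    """
    config = config or AnalysisConfig()
    y = np.asarray(y, dtype=object)
    classes = list(model.classes)
    proba = model.predict_proba(X)
    pred = model.predict(X)
    acc = float((pred == y).mean())
    present = [c for c in classes if (y == c).any()]
    if len(present) < 2:
        auc = np.nan
    elif len(classes) == 2:
        auc = _binary_auc(proba[:, 1], y == classes[1])
    elif config.multiclass_auc == "hand_till":
        auc = _hand_till_auc(proba, y, classes)
    else:  # macro one-vs-rest
        per_class = [
            _binary_auc(proba[:, j], y == c)
            for j, c in enumerate(classes) if (y == c).any() and (y != c).any()
        ]
        auc = float(np.mean(per_class)) if per_class else np.nan
    record = {"accuracy": acc, "auc": auc,
              "flagged_single_class": len(present) < 2}
    for j, c in enumerate(classes):
        tp = ((pred == c) & (y == c)).sum()
        fn = ((pred != c) & (y == c)).sum()
        tn = ((pred != c) & (y != c)).sum()
        fp = ((pred == c) & (y != c)).sum()
        record[f"sens_{c}"] = float(tp / (tp + fn)) if tp + fn else np.nan
        record[f"spec_{c}"] = float(tn / (tn + fp)) if tn + fp else np.nan
    return record


# ----------------------------------------------------------------------
# forward selection and MRCV
# ----------------------------------------------------------------------

def _fit(X: pd.DataFrame, y, class_order, ridge: float) -> SignatureModel:
    return MultinomialLogit(X, y, class_order).fit(ridge=ridge)


def fit_intercept_only(y, class_order, ridge: float = 1e-6) -> SignatureModel:
    empty = pd.DataFrame(index=np.arange(len(np.asarray(y))))
    return _fit(empty, y, class_order, ridge)


def forward_select(
    X: pd.DataFrame,
    y,
    class_order=None,
    delta_bic_stop: float = 2.0,
    ridge: float = 1e-6,
) -> SignatureModel:
    """Greedy forward search from the intercept-only model.

    At each step the candidate minimizing BIC is added iff it improves BIC
    by more than ``delta_bic_stop``; otherwise the search stops.  Ties break
    by fixed feature (column) order; candidates whose fit fails (e.g. exact
    collinearity with the current set) are skipped.
    """
    y = np.asarray(y, dtype=object)
    if class_order is None:
        class_order = tuple(sorted(set(y)))
    selected: list[str] = []
    current = _fit(X[selected], y, class_order, ridge)
    remaining = list(X.columns)
    while remaining:
        best_bic, best_feat, best_model = np.inf, None, None
        for feat in remaining:
            try:
                cand = _fit(X[selected + [feat]], y, class_order, ridge)
            except FitError:
                continue
            if cand.bic < best_bic - 1e-12:
                best_bic, best_feat, best_model = cand.bic, feat, cand
        if best_feat is None or current.bic - best_bic <= delta_bic_stop:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        current = best_model
    return current


def mrcv(
    X: pd.DataFrame,
    y,
    config: AnalysisConfig | None = None,
    seed=0,
    class_order=None,
) -> list[dict]:
    """Multiple random cross-validation on a training subset.

    Each of ``config.mrcv_repeats`` repeats stratifies a 70/30
    teaching/testing split by class, runs forward selection on the teaching
    part, and records MAP accuracies on both parts.  Reproducible from
    ``seed``.
    """
    config = config or AnalysisConfig()
    y = np.asarray(y, dtype=object)
    if class_order is None:
        class_order = tuple(sorted(set(y)))
    for c in class_order:
        n_c = (y == c).sum()
        if n_c < 2:
            raise LipidsigError(
                f"class {c!r} has {n_c} samples; cannot stratify a "
                f"teaching/testing split"
            )
    rng = np.random.default_rng(seed)
    records = []
    class_idx = {c: np.flatnonzero(y == c) for c in class_order}
    for rep in range(config.mrcv_repeats):
        teach, test = [], []
        for c in class_order:
            perm = rng.permutation(class_idx[c])
            n_teach = int(round(config.teach_fraction * len(perm)))
            n_teach = min(max(n_teach, 1), len(perm) - 1)
            teach.extend(perm[:n_teach])
            test.extend(perm[n_teach:])
        teach, test = np.sort(teach), np.sort(test)
        model = forward_select(
            X.iloc[teach], y[teach], class_order,
            delta_bic_stop=config.delta_bic_stop, ridge=config.ridge,
        )
        teach_acc = float((map_classify(model, X.iloc[teach]) == y[teach]).mean())
        test_acc = float((map_classify(model, X.iloc[test]) == y[test]).mean())
        records.append(
            {"repeat": rep, "model": model, "features": model.features,
             "teach_accuracy": teach_acc, "test_accuracy": test_acc}
        )
    return records


# ----------------------------------------------------------------------
# feature ranking and elbow
# ----------------------------------------------------------------------

@dataclass
class FeatureRanking:
    """Selection-frequency ranking of features over a model collection."""

    table: pd.DataFrame        # feature, frequency, mean_order, rank
    elbow_index: int           # number of features kept by the elbow rule
    selected: list[str]
    flagged_empty: bool = False


def rank_features(models) -> FeatureRanking:
    """Rank features by selection frequency across models (descending), then
    mean forward-addition order (ascending), then feature id; cut the ranked
    frequency curve at its largest consecutive drop (the elbow)."""
    feature_sets = [
        m["features"] if isinstance(m, dict) else m.features for m in models
    ]
    if not feature_sets:
        raise LipidsigError("rank_features needs at least one model")
    n_models = len(feature_sets)
    freq: dict[str, int] = {}
    orders: dict[str, list[int]] = {}
    for feats in feature_sets:
        for pos, f in enumerate(feats, start=1):
            freq[f] = freq.get(f, 0) + 1
            orders.setdefault(f, []).append(pos)
    if not freq:
        return FeatureRanking(
            table=pd.DataFrame(columns=["feature", "frequency", "mean_order", "rank"]),
            elbow_index=0, selected=[], flagged_empty=True,
        )
    table = pd.DataFrame(
        {
            "feature": list(freq),
            "frequency": [freq[f] / n_models for f in freq],
            "mean_order": [float(np.mean(orders[f])) for f in freq],
        }
    ).sort_values(
        ["frequency", "mean_order", "feature"],
        ascending=[False, True, True], kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    f = table["frequency"].to_numpy()
    if len(f) == 1:
        elbow = 1
    else:
        drops = f[:-1] - f[1:]
        elbow = int(np.argmax(drops)) + 1
    selected = table["feature"].head(elbow).tolist()
    return FeatureRanking(table=table, elbow_index=elbow, selected=selected)


# ----------------------------------------------------------------------
# outer cross-validation
# ----------------------------------------------------------------------

def _prescreen(X: pd.DataFrame, y, cap: int | None) -> list[str]:
    """Optional candidate cap: keep the ``cap`` features with the smallest
    omnibus rank-test p within the given (training) samples."""
    if cap is None or X.shape[1] <= cap:
        return list(X.columns)
    y = np.asarray(y, dtype=object)
    labels = pd.unique(y)
    masks = [y == g for g in labels]
    pvals = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            pvals.append(1.0)
            continue
        _, p = stats.kruskal(*[x[m] for m in masks])
        pvals.append(p)
    order = np.lexsort((np.arange(len(pvals)), np.asarray(pvals)))
    return [X.columns[i] for i in np.sort(order[:cap])]


class SignatureCV:
    """Nested cross-validated signature search (the outer 8-fold procedure).

    Parameters
    ----------
    values : pandas.DataFrame
        Samples x features matrix (the pipeline feeds permille shares of the
        quantitative tier).
    labels : array-like
        Group label per sample.
    class_order : sequence of str, optional
        Declared ordered class labels (two for a binary model, three for the
        full screen).  Defaults to order of appearance.
    config : AnalysisConfig, optional
    """

    def __init__(self, values: pd.DataFrame, labels, class_order=None,
                 config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        labels = np.asarray(labels, dtype=object)
        if class_order is None:
            class_order = tuple(pd.unique(labels))
        self.classes = tuple(class_order)
        keep = np.isin(labels, self.classes)
        self.values = values.loc[keep]
        self.labels = labels[keep]
        present = set(self.labels)
        absent = [c for c in self.classes if c not in present]
        if absent:
            raise LipidsigError(f"classes with no samples: {absent}")

    @classmethod
    def from_normalized(cls, normalized, class_order=None,
                        config: AnalysisConfig | None = None):
        config = config or AnalysisConfig()
        mat = (normalized.permille if config.feature_scale == "permille"
               else normalized.log2bc[normalized.retained_quant])
        return cls(mat, normalized.groups.to_numpy(),
                   class_order=class_order or normalized.group_order,
                   config=config)

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None) -> "SignatureCVResults":
        config = self.config
        if seed is None:
            seed = config.seed
        y = self.labels
        X = self.values
        rng_root = np.random.SeedSequence(seed)
        part_rng = np.random.default_rng(rng_root.spawn(1)[0])
        fold_seeds = rng_root.spawn(config.outer_folds)

        counts = {c: int((y == c).sum()) for c in self.classes}
        tpg = config.test_per_group
        min_n = min(counts.values())
        if config.outer_folds * tpg > min_n:
            tpg = min_n // config.outer_folds
            if tpg < 1:
                raise LipidsigError(
                    f"cannot draw test samples: smallest class has {min_n} "
                    f"samples for {config.outer_folds} folds"
                )
            warnings.warn(
                f"test_per_group reduced to {tpg} so that "
                f"{config.outer_folds} folds fit the smallest class "
                f"({min_n} samples)", stacklevel=2,
            )
        # non-overlapping test draws without replacement, per group
        fold_test: list[np.ndarray] = [np.array([], dtype=int)] * config.outer_folds
        for c in self.classes:
            perm = part_rng.permutation(np.flatnonzero(y == c))
            for f in range(config.outer_folds):
                fold_test[f] = np.concatenate(
                    [fold_test[f], perm[f * tpg:(f + 1) * tpg]]
                )

        fold_rows, fold_rankings, fold_models, all_models = [], [], [], []
        for f in range(config.outer_folds):
            test_idx = np.sort(fold_test[f])
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            y_train = y[train_mask]
            missing = [c for c in self.classes if not (y_train == c).any()]
            if missing:
                raise LipidsigError(
                    f"fold {f}: classes missing from training remainder: {missing}"
                )
            X_train = X.loc[train_mask]
            candidates = _prescreen(X_train, y_train, config.max_candidate_features)
            records = mrcv(
                X_train[candidates], y_train, config,
                seed=fold_seeds[f], class_order=self.classes,
            )
            all_models.extend(records)
            ranking = rank_features(records)
            fold_rankings.append(ranking)
            model = _fit(
                X_train[ranking.selected], y_train, self.classes, config.ridge
            )
            if len(self.classes) == 2:
                proba_train = model.predict_proba(X_train[ranking.selected])
                model.threshold = youden_threshold(
                    proba_train[:, 1], y_train, positive=self.classes[1]
                )
            fold_models.append(model)
            train_metrics = evaluate(model, X_train, y_train, config)
            test_metrics = evaluate(model, X.iloc[test_idx], y[test_idx], config)
            row = {"fold": f, "signature_size": len(model.features),
                   "signature": ",".join(model.features)}
            row.update({f"train_{k}": v for k, v in train_metrics.items()
                        if not k.startswith("flagged")})
            row.update({f"test_{k}": v for k, v in test_metrics.items()
                        if not k.startswith("flagged")})
            fold_rows.append(row)

        fold_metrics = pd.DataFrame(fold_rows)
        summary_ranking = rank_features(all_models)
        final_model = _fit(
            X[summary_ranking.selected], y, self.classes, config.ridge
        )
        if len(self.classes) == 2:
            proba_all = final_model.predict_proba(X[summary_ranking.selected])
            final_model.threshold = youden_threshold(
                proba_all[:, 1], y, positive=self.classes[1]
            )
        return SignatureCVResults(
            model=self,
            fold_metrics=fold_metrics,
            fold_rankings=fold_rankings,
            fold_models=fold_models,
            summary_ranking=summary_ranking,
            final_model=final_model,
            test_per_group=tpg,
            seed=seed,
        )


@dataclass
class SignatureCVResults:
    """Cross-validation report: per-fold and aggregated metrics, the pooled
    feature ranking with its elbow, and the final refitted model."""

    model: SignatureCV
    fold_metrics: pd.DataFrame
    fold_rankings: list[FeatureRanking]
    fold_models: list[SignatureModel]
    summary_ranking: FeatureRanking
    final_model: SignatureModel
    test_per_group: int
    seed: int

    def aggregate(self) -> pd.DataFrame:
        """Mean and t-based CI over folds for every metric column."""
        ci = self.model.config.ci_level
        folds = len(self.fold_metrics)
        rows = []
        metric_cols = [c for c in self.fold_metrics.columns
                       if c.startswith(("train_", "test_"))]
        tcrit = stats.t.ppf((1 + ci) / 2.0, folds - 1) if folds > 1 else np.nan
        for col in metric_cols:
            x = self.fold_metrics[col].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size == 0:
                rows.append({"metric": col, "mean": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan})
                continue
            mean = float(x.mean())
            if x.size > 1:
                half = tcrit * x.std(ddof=1) / np.sqrt(x.size)
            else:
                half = np.nan
            rows.append({"metric": col, "mean": mean,
                         "ci_low": mean - half, "ci_high": mean + half})
        return pd.DataFrame(rows).set_index("metric")

    @property
    def signature_sizes(self) -> tuple[int, int]:
        sizes = self.fold_metrics["signature_size"]
        return int(sizes.min()), int(sizes.max())

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            "Nested cross-validated signature search",
            "=" * 44,
            f"classes:           {', '.join(self.model.classes)}",
            f"samples:           {len(self.model.labels)}",
            f"features offered:  {self.model.values.shape[1]}",
            f"outer folds:       {len(self.fold_metrics)} "
            f"({self.test_per_group} test samples per group)",
            f"MRCV repeats/fold: {self.model.config.mrcv_repeats}",
            f"signature sizes:   {self.signature_sizes[0]}-{self.signature_sizes[1]}",
            f"final signature ({self.summary_ranking.elbow_index} features): "
            f"{', '.join(self.final_model.features) or '(intercept only)'}",
            "",
            f"{'metric':<18}{'mean':>8}  95% CI",
        ]
        for name in ("train_accuracy", "test_accuracy", "train_auc", "test_auc"):
            if name in agg.index:
                r = agg.loc[name]
                lines.append(
                    f"{name:<18}{r['mean']:>8.3f}  "
                    f"({r['ci_low']:.3f}, {r['ci_high']:.3f})"
                )
        return "\n".join(lines)


def outer_cv(
    normalized_or_values,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    labels=None,
    class_order=None,
) -> SignatureCVResults:
    """Convenience wrapper running the full outer CV.

    Accepts either a :class:`~lipidsig.preprocess.NormalizedPanel` or a raw
    samples x features DataFrame plus ``labels``.
    """
    if labels is None:
        cv = SignatureCV.from_normalized(
            normalized_or_values, class_order=class_order, config=config
        )
    else:
        cv = SignatureCV(normalized_or_values, labels,
                         class_order=class_order, config=config)
    return cv.fit(seed=seed)
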