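"""Maximum-likelihood multinomial logistic regression.

A compact Newton-Raphson fitter specialised for the signature search: models
are tiny (a handful of features, 2-3 classes) but are fitted tens of
thousands of times inside the nested cross-validation, so the solver avoids
any per-fit overhead.  A small ridge penalty on the slopes (default 1e-6,
excluded from the BIC parameter count) keeps separable teaching subsets
finite instead of crashing the forward search.

The first class in ``class_order`` is the reference category; the
coefficient matrix has one column per non-reference class and one row per
feature plus the intercept.  ``BIC = -2 loglik + p ln(n)`` with
``p = (n_features + 1) * (n_classes - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import LipidsigError


class FitError(LipidsigError):
    """Multinomial logit could not be fitted (e.g. collinear features)."""


@dataclass
class SignatureModel:
    """A fitted (multinomial) logistic signature model.

    Attributes
    ----------
    features : tuple of str
        Selected features in forward-addition order.
    classes : tuple of str
        Declared class order; the first class is the reference.
    coef : pandas.DataFrame
        ``(features + intercept) x (classes - 1)`` log-odds coefficients
        relative to the reference class.
    loglik, bic : float
        Unpenalized log-likelihood and its BIC.
    threshold : float or None
        Decision threshold on ``P(second class)`` for binary models (set by
        Youden's J); ``None`` means maximum-a-posteriori classification.
    separable : bool
        Whether the fit hit the ridge-stabilised separation regime.
    """

    features: tuple[str, ...]
    classes: tuple[str, ...]
    coef: pd.DataFrame
    loglik: float
    bic: float
    threshold: float | None = None
    separable: bool = False

    @property
    def n_params(self) -> int:
        return (len(self.features) + 1) * (len(self.classes) - 1)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise FitError(f"feature columns missing from input: {missing}")
        mat = X[list(self.features)].to_numpy(dtype=float)
        return np.hstack([np.ones((len(X), 1)), mat])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Class probabilities, columns ordered as ``self.classes``."""
        design = self._design(X)
        eta = np.hstack(
            [np.zeros((len(design), 1)), design @ self.coef.to_numpy()]
        )
        return np.exp(eta - logsumexp(eta, axis=1, keepdims=True))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """MAP labels (or thresholded labels for binary models)."""
        proba = self.predict_proba(X)
        if self.threshold is not None and len(self.classes) == 2:
            return np.where(
                proba[:, 1] >= self.threshold, self.classes[1], self.classes[0]
            )
        # argmax with deterministic tie-break toward the earlier class
        return np.asarray(self.classes, dtype=object)[proba.argmax(axis=1)]


class MultinomialLogit:
    """Multinomial logistic regression model.

    Parameters
    ----------
    X : pandas.DataFrame
        Samples x features design (an intercept is added internally).
    y : array-like of str
        Class labels.
    class_order : sequence of str, optional
        Declared order; defaults to the sorted unique labels.  The first
        class is the reference.
    """

    def __init__(self, X: pd.DataFrame, y, class_order=None):
        self.X = X
        self.y = np.asarray(y, dtype=object)
        if class_order is None:
            class_order = tuple(sorted(set(self.y)))
        self.classes = tuple(class_order)
        unknown = set(self.y) - set(self.classes)
        if unknown:
            raise FitError(f"labels outside declared class order: {sorted(unknown)}")
        if len(set(self.y)) < 2:
            raise FitError("need at least two classes present to fit")

    def fit(self, ridge: float = 1e-6, max_iter: int = 200, tol: float = 1e-10
            ) -> SignatureModel:
        """Newton-Raphson fit; returns a :class:`SignatureModel`."""
        X, y = self.X, self.y
        n = len(y)
        d = X.shape[1]
        if n <= d + 1:
            raise FitError(
                f"n = {n} samples cannot identify {d} features plus intercept"
            )
        design = np.hstack([np.ones((n, 1)), X.to_numpy(dtype=float)])
        # reject exactly collinear columns up front
        if d > 0:
            rank = np.linalg.matrix_rank(design)
            if rank < d + 1:
                corr_bad = _collinear_columns(X)
                raise FitError(f"rank-deficient features: {corr_bad}")
        K = len(self.classes)
        idx = {c: j for j, c in enumerate(self.classes)}
        Y = np.zeros((n, K))
        Y[np.arange(n), [idx[c] for c in y]] = 1.0
        p = d + 1
        B = np.zeros((p, K - 1))
        slope_mask = np.zeros((p, K - 1))
        slope_mask[1:, :] = 1.0

        def objective(Bm):
            eta = np.hstack([np.zeros((n, 1)), design @ Bm])
            lse = logsumexp(eta, axis=1)
            ll = float((eta * Y).sum() - lse.sum())
            pen = 0.5 * ridge * float((slope_mask * Bm**2).sum())
            P = np.exp(eta - lse[:, None])
            return ll, pen, P

        ll, pen, P = objective(B)
        separable = False
        for _ in range(max_iter):
            G = design.T @ (P[:, 1:] - Y[:, 1:]) + ridge * slope_mask * B
            gnorm = np.abs(G).max()
            if gnorm < 1e-9:
                break
            # Hessian of the penalized NLL, (p(K-1)) x (p(K-1))
            H = np.empty((p * (K - 1), p * (K - 1)))
            for j in range(K - 1):
                for l in range(j, K - 1):
                    w = P[:, j + 1] * ((1.0 if j == l else 0.0) - P[:, l + 1])
                    block = design.T @ (design * w[:, None])
                    H[j * p:(j + 1) * p, l * p:(l + 1) * p] = block
                    if l != j:
                        H[l * p:(l + 1) * p, j * p:(j + 1) * p] = block
            H[np.arange(p * (K - 1)), np.arange(p * (K - 1))] += (
                ridge * slope_mask.T.ravel() + 1e-12
            )
            try:
                step = np.linalg.solve(H, G.T.ravel())
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, G.T.ravel(), rcond=None)[0]
            step = step.reshape(K - 1, p).T
            # step halving on the penalized objective
            obj_old = -(ll) + pen
            alpha = 1.0
            for _half in range(40):
                B_new = B - alpha * step
                ll_new, pen_new, P_new = objective(B_new)
                if -(ll_new) + pen_new <= obj_old + 1e-12:
                    break
                alpha *= 0.5
            if abs((-(ll_new) + pen_new) - obj_old) < tol * (1.0 + abs(obj_old)):
                B, ll, pen, P = B_new, ll_new, pen_new, P_new
                break
            B, ll, pen, P = B_new, ll_new, pen_new, P_new
        if np.abs(B[1:, :]).max(initial=0.0) * ridge > 1e-3:
            separable = True  # slopes diverged into the ridge-dominated regime
        n_params = p * (K - 1)
        bic = -2.0 * ll + n_params * np.log(n)
        coef = pd.DataFrame(
            B,
            index=["intercept"] + list(X.columns),
            columns=[f"{c}_vs_{self.classes[0]}" for c in self.classes[1:]],
        )
        return SignatureModel(
            features=tuple(X.columns),
            classes=self.classes,
            coef=coef,
            loglik=ll,
            bic=bic,
            separable=separable,
        )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns involved in exact linear dependence (for error messages)."""
    cols = list(X.columns)
    bad = []
    arr = np.hstack([np.ones((len(X), 1)), X.to_numpy(dtype=float)])
    for j in range(1, arr.shape[1]):
        if np.linalg.matrix_rank(arr[:, : j + 1]) < j + 1:
            bad.append(cols[j - 1])
    return bad
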