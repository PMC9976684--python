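"""Two-class PLS-DA with unit-variance scaling and cross-validated Q2.

The model regresses a +/-1 class encoding on unit-variance-scaled features by
NIPALS partial least squares (deflation of X only), reporting per-component
and cumulative R2X, R2Y on the training data and a stratified tenfold
cross-validated Q2 = 1 - PRESS/TSS, with scaling re-estimated inside each
training fold so no information leaks from held-out samples.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def _encode_labels(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"PLS-DA requires exactly 2 classes, got {len(classes)}")
    enc = np.where(y == classes[1], 1.0, -1.0)
    return classes, enc


class PLSDiscriminant(BaseEstimator, ClassifierMixin):
    """NIPALS PLS-DA for a binary class response.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components (two suffices for score plots and is the
        default readout depth). Truncated with a warning when the data rank
        is lower.
    scale : bool, default True
        Unit-variance scale each feature (columns are always centered).
    max_iter, tol :
        NIPALS inner-loop controls per component.

    Attributes
    ----------
    classes_ : the two class labels, sorted; the second is encoded +1.
    x_weights_, x_loadings_, x_scores_, y_loadings_ : NIPALS quantities,
        one column (or entry) per component. Each weight vector's
        largest-magnitude element is made positive for reproducibility.
    r2x_, r2y_ : per-component explained variance of X and of the encoded
        response; ``r2x_cum_`` / ``r2y_cum_`` are their cumulative sums.
    dropped_features_ : indices of zero-variance columns excluded from the fit.
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        self.classes_, y_enc = _encode_labels(y)
        for cls in self.classes_:
            if (np.asarray(y) == cls).sum() < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n, p = X.shape

        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.dropped_features_ = np.where(sd == 0)[0]
        if len(self.dropped_features_):
            logger.info("dropping %d zero-variance feature(s)", len(self.dropped_features_))
        self.kept_features_ = np.where(sd > 0)[0]
        self.x_scale_ = np.where(sd > 0, sd, 1.0) if self.scale else np.ones(p)
        Xs = (X - self.x_mean_) / self.x_scale_
        Xs = Xs[:, self.kept_features_]

        self.y_mean_ = y_enc.mean()
        yc = y_enc - self.y_mean_
        tss_y = float(yc @ yc)
        tss_x = float((Xs**2).sum())

        max_rank = min(n - 1, Xs.shape[1])
        n_comp = min(self.n_components, max_rank)
        if n_comp < self.n_components:
            warnings.warn(
                f"n_components={self.n_components} exceeds rank bound {max_rank}; "
                f"truncated to {n_comp}", UserWarning,
            )

        E = Xs.copy()
        W, P, T, C = [], [], [], []
        r2x, r2y = [], []
        resid = yc.copy()
        for _ in range(n_comp):
            if float((E**2).sum()) <= 1e-12 * max(tss_x, 1.0):
                warnings.warn("X fully deflated; stopping early", UserWarning)
                break
            # NIPALS inner loop (degenerates to one pass for a single response)
            u = resid if float(resid @ resid) > 0 else yc
            w_old = None
            for _ in range(self.max_iter):
                w = E.T @ u
                norm = np.linalg.norm(w)
                if norm == 0:
                    break
                w = w / norm
                t = E @ w
                c = float(yc @ t) / float(t @ t)
                u = yc * c
                if w_old is not None and np.linalg.norm(w - w_old) < self.tol:
                    break
                w_old = w
            if np.linalg.norm(w) == 0:
                break
            # sign convention: largest-|w| element positive
            imax = int(np.argmax(np.abs(w)))
            if w[imax] < 0:
                w, t, c = -w, -t, -c
            pvec = E.T @ t / float(t @ t)
            E = E - np.outer(t, pvec)
            W.append(w); P.append(pvec); T.append(t); C.append(c)
            r2x.append(float((np.outer(t, pvec) ** 2).sum()) / tss_x)
            resid = resid - t * c
            r2y.append((1.0 - float(resid @ resid) / tss_y) - sum(r2y))

        self.x_weights_ = np.column_stack(W) if W else np.zeros((Xs.shape[1], 0))
        self.x_loadings_ = np.column_stack(P) if P else np.zeros((Xs.shape[1], 0))
        self.x_scores_ = np.column_stack(T) if T else np.zeros((n, 0))
        self.y_loadings_ = np.asarray(C)
        self.r2x_ = np.asarray(r2x)
        self.r2y_ = np.asarray(r2y)
        self.r2x_cum_ = np.cumsum(self.r2x_)
        self.r2y_cum_ = np.cumsum(self.r2y_)
        self.n_components_ = len(W)
        # regression vector in scaled space: B = W (P'W)^-1 C
        if self.n_components_:
            PtW = self.x_loadings_.T @ self.x_weights_
            self.coef_path_ = [
                self.x_weights_[:, :a] @ np.linalg.solve(
                    PtW[:a, :a], self.y_loadings_[:a]
                )
                for a in range(1, self.n_components_ + 1)
            ]
            self.coef_ = self.coef_path_[-1]
        else:
            self.coef_path_ = []
            self.coef_ = np.zeros(Xs.shape[1])
        return self

    # -- inference ---------------------------------------------------------
    def _scaled(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return ((X - self.x_mean_) / self.x_scale_)[:, self.kept_features_]

    def transform(self, X) -> np.ndarray:
        """Project samples onto the latent components (scores)."""
        check_is_fitted(self, "x_weights_")
        E = self._scaled(X)
        T = np.zeros((E.shape[0], self.n_components_))
        for a in range(self.n_components_):
            t = E @ self.x_weights_[:, a]
            T[:, a] = t
            E = E - np.outer(t, self.x_loadings_[:, a])
        return T

    def decision_function(self, X, n_components: int | None = None) -> np.ndarray:
        """Predicted continuous response on the +/-1 encoding scale."""
        check_is_fitted(self, "coef_")
        a = self.n_components_ if n_components is None else n_components
        if not (1 <= a <= self.n_components_):
            raise ValueError(f"n_components must be in [1, {self.n_components_}]")
        return self._scaled(X) @ self.coef_path_[a - 1] + self.y_mean_

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def cross_validated_q2(
    X,
    y,
    n_components: int = 2,
    n_splits: int = 10,
    seed: int = 0,
    scale: bool = True,
    leak_full_scaling: bool = False,
) -> np.ndarray:
    """Cumulative Q2 per component from stratified k-fold cross-validation.

    Q2(a) = 1 - PRESS(a)/TSS where PRESS sums squared held-out prediction
    errors of the +/-1 encoded response using the first ``a`` components,
    and TSS is taken from the full centered response. Scaling and centering
    are re-estimated inside each training fold; ``leak_full_scaling=True``
    deliberately pre-scales on the full data (a diagnostic for leakage
    tests, never for reporting).
    """
    X = np.asarray(X, dtype=float)
    classes, y_enc = _encode_labels(y)
    tss = float(((y_enc - y_enc.mean()) ** 2).sum())

    if leak_full_scaling:
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)

    min_class = int(min(np.sum(np.asarray(y) == cls) for cls in classes))
    if n_splits > min_class:
        warnings.warn(
            f"n_splits={n_splits} exceeds smallest class ({min_class}); reduced",
            UserWarning,
        )
        n_splits = min_class
    press = np.zeros(n_components)
    fitted_comps = n_components
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(X, np.asarray(y)))
        if all(len(np.unique(np.asarray(y)[tr])) == 2 for tr, _ in folds):
            break
        warnings.warn("a training split missed a class; refolding", UserWarning)
    press[:] = 0.0
    for tr, te in folds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = PLSDiscriminant(
                n_components=n_components,
                scale=scale and not leak_full_scaling,
            ).fit(X[tr], np.asarray(y)[tr])
        fitted_comps = min(fitted_comps, model.n_components_)
        for a in range(1, n_components + 1):
            a_eff = min(a, model.n_components_)
            pred = model.decision_function(X[te], n_components=a_eff)
            press[a - 1] += float(((y_enc[te] - pred) ** 2).sum())
    return 1.0 - press / tss
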