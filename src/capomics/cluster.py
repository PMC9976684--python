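"""Fuzzy c-means clustering of standardized group-mean trend profiles.

Differential features are summarized as a 3-point profile of group means over
(CON, NS_CAP, S_CAP), standardized per feature to zero mean and unit variance,
and soft-clustered Mfuzz-style: each feature receives a graded membership in
every cluster, governed by the fuzzifier m. Cluster centers are then labeled
increasing / decreasing / inverted-V / other by their shape.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .io import GROUPS, IntensityTable, align

logger = logging.getLogger(__name__)

TREND_LABELS = ("increasing", "decreasing", "inverted_V", "other")


def group_mean_profiles(
    table: IntensityTable,
    metadata: pd.DataFrame,
    feature_ids: Sequence[str] | None = None,
    groups: Sequence[str] = GROUPS,
    cohort: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature standardized group-mean profiles.

    Returns ``(profiles, excluded)``: a features x groups DataFrame with each
    row standardized to zero mean and unit sample variance, plus the ids of
    constant-profile features that were excluded. Standardization makes
    profiles invariant to any positive rescaling of raw intensities.
    """
    means = {}
    for g in groups:
        sub = align(table, metadata, groups=[g], cohort=cohort)
        means[g] = sub.values.mean(axis=1, skipna=True)
    prof = pd.DataFrame(means)
    if feature_ids is not None:
        prof = prof.loc[list(feature_ids)]
    if prof.isna().any().any():
        bad = prof.index[prof.isna().any(axis=1)]
        raise ValueError(f"feature(s) with no present values in a group: {list(bad)[:5]}")
    mu = prof.mean(axis=1)
    sd = prof.std(axis=1, ddof=1)  # sample sd: (1,2,3) -> (-1,0,1)
    excluded = list(prof.index[sd == 0])
    if excluded:
        logger.info("excluding %d constant profile(s)", len(excluded))
    prof = prof.loc[sd > 0]
    out = prof.sub(mu[prof.index], axis=0).div(sd[prof.index], axis=0)
    return out, excluded


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means with alternating membership/center updates.

    Memberships follow ``u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1))``; centers
    are ``u^m``-weighted means. Iteration stops when the objective
    ``J = sum u^m d^2`` changes by less than ``tol``. A profile coinciding
    with a center takes membership 1 there (limit convention). Centers are
    initialized from ``n_clusters`` distinct rows drawn by the seeded
    generator (ties broken by lowest row index).

    Attributes
    ----------
    cluster_centers_ : (k, d) array
    membership_ : (n, k) array, rows summing to 1
    objective_trace_ : objective value after each iteration (non-increasing)
    labels_ : hard argmax-membership assignment of the training data
    """

    def __init__(self, n_clusters: int = 4, m: float = 1.25,
                 max_iter: int = 200, tol: float = 1e-9, random_state: int = 0):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = np.zeros((X.shape[0], centers.shape[0]))
        zero = d2 <= 1e-300
        any_zero = zero.any(axis=1)
        if any_zero.any():
            for i in np.where(any_zero)[0]:
                u[i, int(np.argmax(zero[i]))] = 1.0
        rest = ~any_zero
        if rest.any():
            # softmax-style evaluation of d2^(-1/(m-1)) keeps small fuzzifiers
            # (large exponents) from overflowing
            logits = -np.log(d2[rest]) / (self.m - 1.0)
            logits -= logits.max(axis=1, keepdims=True)
            power = np.exp(logits)
            u[rest] = power / power.sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        if n <= self.n_clusters:
            raise ValueError(f"need more profiles ({n}) than clusters ({self.n_clusters})")

        rng = np.random.default_rng(self.random_state)
        # distinct initial centers: unique rows, seeded choice, lowest-index ties
        _, first_idx = np.unique(np.round(X, 12), axis=0, return_index=True)
        first_idx = np.sort(first_idx)
        if len(first_idx) < self.n_clusters:
            raise ValueError("fewer distinct profiles than clusters")
        chosen = np.sort(rng.choice(first_idx, size=self.n_clusters, replace=False))
        centers = X[chosen].copy()

        trace: list[float] = []
        u = self._memberships(X, centers)
        for _ in range(self.max_iter):
            um = u**self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            u = self._memberships(X, centers)
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            obj = float((u**self.m * d2).sum())
            if trace and abs(trace[-1] - obj) < self.tol:
                trace.append(obj)
                break
            trace.append(obj)

        self.cluster_centers_ = centers
        self.membership_ = u
        self.objective_trace_ = trace
        self.labels_ = np.argmax(u, axis=1)
        self.n_iter_ = len(trace)
        return self

    def predict_membership(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        return self._memberships(np.asarray(X, dtype=float), self.cluster_centers_)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_membership(X), axis=1)


def label_center(center: Sequence[float], slack: float = 0.1) -> str:
    """Label a 3-point (CON, NS_CAP, S_CAP) center by its shape.

    ``slack`` (standardized units) separates genuinely monotone centers from
    flat ones: increasing requires a net rise above slack with no drop larger
    than slack at either step; decreasing mirrors it; inverted-V requires the
    middle point to top both ends by more than slack.
    """
    c0, c1, c2 = (float(v) for v in center)
    if c1 > c0 + slack and c1 > c2 + slack:
        return "inverted_V"
    if c2 > c1 - slack and c1 > c0 - slack and c2 > c0 + slack:
        return "increasing"
    if c2 < c1 + slack and c1 < c0 + slack and c2 < c0 - slack:
        return "decreasing"
    return "other"


def assign_trend_labels(
    model: FuzzyCMeans,
    profiles: pd.DataFrame,
    membership_floor: float = 0.5,
    slack: float = 0.1,
) -> tuple[pd.Series, dict[int, str]]:
    """Map each feature to its max-membership cluster's trend label.

    A feature whose top membership falls below ``membership_floor`` is
    labeled ``"other"``. Returns (per-feature labels, per-cluster labels).
    """
    check_is_fitted(model, "cluster_centers_")
    cluster_labels = {
        j: label_center(model.cluster_centers_[j], slack=slack)
        for j in range(model.cluster_centers_.shape[0])
    }
    u = model.predict_membership(profiles.to_numpy())
    top = np.argmax(u, axis=1)
    top_u = u[np.arange(len(u)), top]
    labels = [
        cluster_labels[j] if tu >= membership_floor else "other"
        for j, tu in zip(top, top_u)
    ]
    return pd.Series(labels, index=profiles.index, name="trend"), cluster_labels
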