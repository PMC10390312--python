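"""Unsupervised derivation of drinking groups.

K-means (Lloyd's algorithm, multiple seeded restarts, squared-Euclidean
within-cluster sum of squares) partitions respondents on the candidate
items; the elbow of the WCSS curve selects the number of groups; derived
clusters are then relabelled 1..K in increasing drinking severity so that
group indices carry ordinal meaning for the downstream ordinal model.

Severity of a cluster is scored as the mean of its centroid coordinates
after per-item z-scoring against the training sample (so items on very
different scales weigh equally in the ranking), with ties broken by the
raw drunkenness-frequency centroid.  No variable standardisation is
applied before clustering itself by default: the derived structure is
dominated by the raw drunkenness count, and the published group means
reflect unscaled items.  A z-score option is provided.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .survey import DRUNKENNESS_COL, ITEM_FIELDS


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One Lloyd run from a random-row initialisation.

    Returns (centers, labels, per-iteration WCSS trace).  An empty cluster
    is re-seeded at the point farthest from its current centroid.
    """
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    trace: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(n), new_labels].sum())
        for c in range(k):
            mask = new_labels == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
            else:
                far = d2[np.arange(n), new_labels].argmax()
                centers[c] = X[far]
                new_labels[far] = c
        trace.append(wcss)
        if np.array_equal(new_labels, labels) or (
            len(trace) > 1 and trace[-2] - trace[-1] < tol
        ):
            labels = new_labels
            break
        labels = new_labels
    # final WCSS at the converged assignment/centroids
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    trace.append(float(d2[np.arange(n), labels].sum()))
    return centers, labels, trace


def severity_order(centers: np.ndarray, item_scales: np.ndarray,
                   drunk_col: int = DRUNKENNESS_COL) -> np.ndarray:
    """Return cluster indices sorted by ascending severity score.

    Severity = mean of z-scored centroid coordinates; ties broken by the
    raw drunkenness-frequency centroid.
    """
    scales = np.where(item_scales > 0, item_scales, 1.0)
    z = (centers - centers.mean(axis=0)) / scales
    score = z.mean(axis=1)
    return np.lexsort((centers[:, drunk_col], score))


class KMeansGroupDeriver(ClusterMixin, BaseEstimator):
    """K-means with severity-ranked cluster labels (1..K).

    Parameters
    ----------
    n_clusters : int
        Number of groups to derive (4 in the published model).
    n_restarts : int
        Independent Lloyd restarts; the run with the lowest WCSS wins.
    tol : float
        Minimum WCSS improvement to continue iterating.
    standardize : bool
        Z-score items before clustering (off by default; see module notes).
    drunk_col : int
        Column used to break severity ties (drunkenness frequency).
    random_state : int
        Seed; required for reproducible restarts.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (K, p)
        Centroids in severity order (row 0 = group 1), on the original scale.
    labels_ : ndarray
        Severity-ranked group index (1..K) per training row.
    inertia_ : float
        WCSS of the winning run.
    wcss_trace_ : list of float
        Per-iteration WCSS of the winning run (non-increasing).
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_restarts: int = 25,
        max_iter: int = 300,
        tol: float = 1e-8,
        standardize: bool = False,
        drunk_col: int = DRUNKENNESS_COL,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize
        self.drunk_col = drunk_col
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D item matrix")
        n, p = X.shape
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > n:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds {n} rows")

        self.scale_mean_ = X.mean(axis=0)
        self.scale_sd_ = X.std(axis=0)
        Xw = (X - self.scale_mean_) / np.where(self.scale_sd_ > 0, self.scale_sd_, 1.0) \
            if self.standardize else X

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            centers, labels, trace = _lloyd(Xw, self.n_clusters, rng, self.max_iter, self.tol)
            if best is None or trace[-1] < best[2][-1]:
                best = (centers, labels, trace)
        centers, labels, trace = best

        # undo working-scale transform for reporting/ranking
        if self.standardize:
            centers_orig = centers * np.where(self.scale_sd_ > 0, self.scale_sd_, 1.0) \
                + self.scale_mean_
        else:
            centers_orig = centers
        drunk = min(self.drunk_col, p - 1)
        order = severity_order(centers_orig, self.scale_sd_, drunk)
        rank_of = np.empty(self.n_clusters, int)
        rank_of[order] = np.arange(1, self.n_clusters + 1)

        self._centers_working_ = centers[order]
        self.cluster_centers_ = centers_orig[order]
        self.labels_ = rank_of[labels]
        self.inertia_ = trace[-1]
        self.wcss_trace_ = trace
        self.n_iter_ = len(trace)
        return self

    def predict(self, X) -> np.ndarray:
        """Assign new rows to the nearest centroid's severity-ranked group."""
        X = np.asarray(X, float)
        if self.standardize:
            X = (X - self.scale_mean_) / np.where(self.scale_sd_ > 0, self.scale_sd_, 1.0)
        d2 = ((X[:, None, :] - self._centers_working_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1) + 1

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def kmeans(
    items, n_clusters: int = 4, seed: int = 0, n_restarts: int = 25, **kwargs
) -> KMeansGroupDeriver:
    """Fit a :class:`KMeansGroupDeriver` on an item matrix (thin wrapper)."""
    return KMeansGroupDeriver(
        n_clusters=n_clusters, n_restarts=n_restarts, random_state=seed, **kwargs
    ).fit(np.asarray(items, float))


def knee_from_curve(k_values, wcss) -> int:
    """Knee of a WCSS-vs-K curve: K maximising the discrete second difference.

    Ties go to the smaller K.  A non-monotone curve (failed restarts) only
    triggers a warning; the knee is computed regardless.
    """
    k_values = list(k_values)
    wcss = np.asarray(wcss, float)
    if len(k_values) < 3:
        raise ValueError("need at least 3 K values to locate a knee")
    if np.any(np.diff(wcss) > 0):
        warnings.warn("WCSS curve is not non-increasing; knee may be unreliable")
    second = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]
    return k_values[1 + int(np.argmax(second))]


def elbow_select_k(
    items,
    k_range=range(2, 9),
    seed: int = 0,
    n_restarts: int = 10,
    **kwargs,
) -> tuple[int, pd.DataFrame]:
    """Scan K over ``k_range``, return (knee K, WCSS curve for plotting)."""
    X = np.asarray(items, float)
    ks = sorted(k_range)
    wcss = []
    for k in ks:
        model = KMeansGroupDeriver(
            n_clusters=k, n_restarts=n_restarts, random_state=seed, **kwargs
        ).fit(X)
        wcss.append(model.inertia_)
    curve = pd.DataFrame({"K": ks, "wcss": wcss})
    return knee_from_curve(ks, wcss), curve


def rank_clusters(labels, centers, item_scales=None,
                  drunk_col: int = DRUNKENNESS_COL) -> tuple[np.ndarray, np.ndarray]:
    """Severity-relabel an arbitrary clustering (pure permutation).

    Returns (relabelled 1..K labels, centroids reordered to severity order);
    the multiset of centroids is unchanged.
    """
    centers = np.asarray(centers, float)
    if item_scales is None:
        item_scales = centers.std(axis=0)
    order = severity_order(centers, np.asarray(item_scales, float),
                           min(drunk_col, centers.shape[1] - 1))
    rank_of = np.empty(len(centers), int)
    rank_of[order] = np.arange(1, len(centers) + 1)
    return rank_of[np.asarray(labels, int)], centers[order]


def cluster_means(labels, items, item_names=None) -> pd.DataFrame:
    """Per-group arithmetic item means, rows in severity (label) order."""
    X = np.asarray(items, float)
    if item_names is None:
        item_names = list(ITEM_FIELDS[: X.shape[1]]) if X.shape[1] <= len(ITEM_FIELDS) \
            else [f"item_{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=item_names)
    df["group"] = np.asarray(labels, int)
    out = df.groupby("group").mean().sort_index()
    out.insert(0, "n", df.groupby("group").size())
    return out
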