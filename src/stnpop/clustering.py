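"""Window-based functional clustering of response profiles.

Neurons are represented by two numbers — the mean z-scored response in the
100-300 ms window after onset of a contralateral good object and of a
contralateral bad object — and partitioned with k-means.  The number of
clusters is chosen by repeating k-means many times per candidate K with fresh
random initializations and taking the K with the highest mean silhouette.
The three canonical profiles are labeled:

1. facilitative, good > bad (both features positive, good larger);
2. value-coding bidirectional (most-negative bad feature);
3. bad-preferring (bad > good among the remainder).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .processing import AlignedActivity, epoch_mean

logger = logging.getLogger(__name__)

FEATURE_WINDOW_MS = (100.0, 300.0)

__all__ = [
    "build_features",
    "select_k",
    "assign_clusters",
    "canonicalize_labels",
    "compare_baseline_rates",
    "ResponseProfileClusterer",
]


def build_features(
    aligned_z: AlignedActivity,
    trials: pd.DataFrame,
    window_ms: tuple[float, float] = FEATURE_WINDOW_MS,
) -> pd.DataFrame:
    """Per-neuron (good, bad) window features from target-aligned z activity.

    Trials are restricted to contralateral presentations; activity is averaged
    over the window per trial, then across trials within each value condition.
    Neurons missing either condition (or excluded upstream for zero baseline
    SD) are dropped with a warning.
    """
    if aligned_z.alignment != "target":
        raise ValueError("clustering features require target-aligned activity")
    em = epoch_mean(aligned_z, window_ms)  # (n_neurons, n_trials)

    tinfo = trials.set_index("trial_id")
    feats = {}
    for i, nid in enumerate(aligned_z.neuron_ids):
        tids = aligned_z.trial_ids[i]
        valid = tids >= 0
        tt = tinfo.loc[tids[valid]]
        vals = em[i, valid]
        contra = (tt["direction"] == "contra").to_numpy()
        row = []
        for value in ("good", "bad"):
            sel = contra & (tt["value"] == value).to_numpy()
            sel &= np.isfinite(vals)
            row.append(vals[sel].mean() if sel.any() else np.nan)
        feats[nid] = row
    df = pd.DataFrame.from_dict(
        feats, orient="index", columns=["z_good", "z_bad"]
    ).rename_axis("neuron_id")
    bad = df.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} neurons excluded from clustering features "
            "(missing condition or undefined z)",
            stacklevel=2,
        )
    return df.loc[~bad]


def _as_matrix(features) -> np.ndarray:
    X = features.to_numpy(dtype=float) if hasattr(features, "to_numpy") else np.asarray(
        features, dtype=float
    )
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    return X


def select_k(
    features,
    k_range: range = range(2, 7),
    n_repeats: int = 5000,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Choose K by the highest mean silhouette over repeated k-means runs.

    Each repeat is an independently initialized k-means fit (``n_restarts``
    k-means++ starts, best inertia kept) whose partition is scored with the
    mean silhouette.  Returns ``(silhouette_table, chosen_k)`` where the table
    has one row per K with the mean/SD silhouette over repeats.
    """
    X = _as_matrix(features)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate features: all rows identical, not clusterable")
    if len(X) <= max(k_range):
        raise ValueError("need more observations than the largest candidate K")
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        sils = np.empty(n_repeats)
        for r in range(n_repeats):
            km = KMeans(
                n_clusters=k,
                n_init=n_restarts,
                init="k-means++",
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X)
            sils[r] = silhouette_score(X, km.labels_)
        rows.append((k, sils.mean(), sils.std(ddof=1) if n_repeats > 1 else 0.0))
    table = pd.DataFrame(rows, columns=["k", "mean_silhouette", "sd_silhouette"])
    chosen = int(table.loc[table["mean_silhouette"].idxmax(), "k"])
    return table, chosen


def assign_clusters(
    features, k: int, seed: int = 0, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Best-of-restarts k-means partition; deterministic given the seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _as_matrix(features)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    return km.labels_, km.cluster_centers_


def canonicalize_labels(
    labels: np.ndarray, centroids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary k-means labels onto the canonical profiles 1/2/3.

    Only defined for K = 3 (other K pass through unchanged with a warning).
    Label 2 is the centroid with the most negative bad feature; among the
    remaining two, label 1 has the larger good-minus-bad margin (ties broken
    by good feature descending, logged).  Returns ``(labels_1based,
    centroids_reordered)`` with ``centroids_reordered[j]`` the centroid of
    canonical label ``j + 1``.
    """
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) != 3:
        warnings.warn("canonical labels are defined for K=3 only; passing through")
        return np.asarray(labels) + 1, centroids
    good, bad = centroids[:, 0], centroids[:, 1]
    c2 = int(np.argmin(bad))
    rest = [i for i in range(3) if i != c2]
    margin = good[rest] - bad[rest]
    if margin[0] == margin[1]:
        logger.info("centroid margin tie; breaking by good feature descending")
        order = np.argsort(-good[rest], kind="stable")
    else:
        order = np.argsort(-margin, kind="stable")
    c1, c3 = rest[order[0]], rest[order[1]]
    mapping = {c1: 1, c2: 2, c3: 3}
    new_labels = np.array([mapping[int(l)] for l in np.asarray(labels)])
    new_centroids = centroids[[c1, c2, c3]]
    return new_labels, new_centroids


def compare_baseline_rates(
    rates: pd.Series | np.ndarray, assignments: np.ndarray
) -> tuple[float, float]:
    """Kruskal-Wallis test of baseline firing rate across clusters."""
    rates = np.asarray(rates, dtype=float)
    assignments = np.asarray(assignments)
    groups = [rates[assignments == g] for g in np.unique(assignments)]
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty cluster group")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


class ResponseProfileClusterer(BaseEstimator, ClusterMixin):
    """K-means functional clustering with repeated-silhouette K selection.

    Parameters
    ----------
    k : int or None
        Fixed number of clusters; if None, selected by the silhouette
        procedure over ``k_range``.
    k_range : tuple
        Inclusive (low, high) candidate range for K selection.
    n_repeats : int
        Random-initialization repeats per candidate K (5000 reproduces the
        full procedure; smaller values are fine at desk scale).
    n_restarts : int
        k-means++ restarts per repeat and for the final assignment.
    canonical : bool
        Relabel a K=3 solution onto the canonical profile labels 1/2/3.
    random_state : int

    Attributes
    ----------
    silhouette_by_k_ : pandas.DataFrame (absent when ``k`` is fixed)
    k_ : int
    labels_ : ndarray, canonical 1-based labels when ``canonical`` and K=3,
        else raw 0-based k-means labels offset to 1-based.
    centroids_ : ndarray ordered by canonical label.
    """

    def __init__(
        self,
        k: int | None = None,
        k_range: tuple[int, int] = (2, 6),
        n_repeats: int = 5000,
        n_restarts: int = 10,
        canonical: bool = True,
        random_state: int = 0,
    ):
        self.k = k
        self.k_range = k_range
        self.n_repeats = n_repeats
        self.n_restarts = n_restarts
        self.canonical = canonical
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.k is None:
            self.silhouette_by_k_, self.k_ = select_k(
                X,
                k_range=range(self.k_range[0], self.k_range[1] + 1),
                n_repeats=self.n_repeats,
                seed=self.random_state,
                n_restarts=self.n_restarts,
            )
        else:
            self.k_ = int(self.k)
        labels, centroids = assign_clusters(
            X, self.k_, seed=self.random_state, n_restarts=self.n_restarts
        )
        if self.canonical and self.k_ == 3:
            self.labels_, self.centroids_ = canonicalize_labels(labels, centroids)
        else:
            self.labels_, self.centroids_ = labels + 1, centroids
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
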