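"""Data-driven validation of the functional groupings.

The trial-averaged z-scored responses to contralateral good and bad objects
(0-300 ms after target onset, 1-ms bins) are stacked as separate rows — 2N
rows for N neurons — each time column is centered and scaled, and the matrix
is decomposed with PCA.  Each neuron's scores on PC1-3 for the good and bad
rows form a 6-D feature vector that is re-clustered with k-means at K = 2
and K = 3; agreement with the window-based clusters is reported as a
cross-tabulation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .processing import AlignedActivity

RESPONSE_WINDOW_MS = (0.0, 300.0)

__all__ = [
    "build_stacked_matrix",
    "fit_pca",
    "pc_score_features",
    "cluster_pc_space",
    "StackedConditionPCA",
]


def build_stacked_matrix(
    aligned_z: AlignedActivity,
    trials: pd.DataFrame,
    window_ms: tuple[float, float] = RESPONSE_WINDOW_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-neuron trial-averaged good/bad responses into a 2N x T matrix.

    Row order: all good-condition rows (neuron order), then all bad-condition
    rows.  Only contralateral trials contribute.  Neurons missing either
    condition lose both rows.  Returns ``(matrix, neuron_ids)``.
    """
    tmask = (aligned_z.time_ms >= window_ms[0]) & (aligned_z.time_ms < window_ms[1])
    if not tmask.any():
        raise ValueError("response window outside the aligned time axis")
    tinfo = trials.set_index("trial_id")
    good_rows, bad_rows, kept = [], [], []
    for i, nid in enumerate(aligned_z.neuron_ids):
        tids = aligned_z.trial_ids[i]
        valid = tids >= 0
        tt = tinfo.loc[tids[valid]]
        vals = aligned_z.values[i, valid][:, tmask].astype(np.float64)
        contra = (tt["direction"] == "contra").to_numpy()
        rows = {}
        for value in ("good", "bad"):
            sel = contra & (tt["value"] == value).to_numpy()
            if sel.any() and np.isfinite(vals[sel]).all():
                rows[value] = vals[sel].mean(axis=0)
        if len(rows) == 2:
            good_rows.append(rows["good"])
            bad_rows.append(rows["bad"])
            kept.append(nid)
        else:
            warnings.warn(f"neuron {nid} excluded from stacked PCA", stacklevel=2)
    if not kept:
        raise ValueError("no neurons with both conditions")
    return np.vstack(good_rows + bad_rows), np.asarray(kept)


def fit_pca(matrix: np.ndarray):
    """Column-standardized PCA of the stacked response matrix.

    Each time column is centered and scaled to unit SD (zero-variance columns
    are dropped with a warning), then decomposed.  Component signs are fixed
    so each loading's largest-magnitude element is positive.  Returns
    ``(loadings, scores, explained_variance_ratio)`` with loadings of shape
    (n_components, n_kept_columns).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance time columns dropped", stacklevel=2
        )
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    pca = PCA()
    scores = pca.fit_transform(Xs)
    loadings = pca.components_
    # Deterministic sign convention.
    flip = np.sign(loadings[np.arange(len(loadings)), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    return loadings, scores, pca.explained_variance_ratio_


def pc_score_features(scores: np.ndarray, n_neurons: int) -> np.ndarray:
    """Fold stacked-row PC1-3 scores into an N x 6 per-neuron feature matrix.

    Column order: (PC1, PC2, PC3) for the good row then for the bad row.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != 2 * n_neurons:
        raise ValueError(
            f"score rows ({scores.shape[0]}) != 2 x neurons ({n_neurons})"
        )
    if scores.shape[1] < 3:
        raise ValueError("need at least three components")
    return np.hstack([scores[:n_neurons, :3], scores[n_neurons:, :3]])


def cluster_pc_space(
    features: np.ndarray,
    ks: tuple[int, ...] = (2, 3),
    seed: int = 0,
    reference_labels: np.ndarray | None = None,
):
    """K-means in the 6-D PC-score space for each requested K.

    Returns a dict ``{k: labels}`` plus, when ``reference_labels`` is given,
    a dict of cross-tabulations against the window-based assignment.
    """
    features = np.asarray(features, dtype=float)
    assignments = {}
    crosstabs = {}
    for k in ks:
        km = KMeans(n_clusters=int(k), n_init=10, random_state=seed).fit(features)
        assignments[int(k)] = km.labels_
        if reference_labels is not None:
            crosstabs[int(k)] = pd.crosstab(
                pd.Series(reference_labels, name="window_cluster"),
                pd.Series(km.labels_, name=f"pc_cluster_k{k}"),
            )
    return (assignments, crosstabs) if reference_labels is not None else assignments


class StackedConditionPCA(BaseEstimator, TransformerMixin):
    """PCA over stacked good/bad condition responses, sklearn style.

    ``fit(X)`` expects the 2N x T stacked matrix; ``transform`` returns the
    N x 6 PC-score feature matrix.

    Attributes
    ----------
    loadings_ : ndarray (components x kept time columns)
    scores_ : ndarray (2N x components)
    explained_variance_ratio_ : ndarray
    features_ : ndarray (N x 6)
    assignments_ : dict of K -> labels (after ``cluster``)
    """

    def __init__(self, ks: tuple[int, ...] = (2, 3), random_state: int = 0):
        self.ks = ks
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] % 2:
            raise ValueError("stacked matrix must have an even number of rows")
        self.n_neurons_ = X.shape[0] // 2
        self.loadings_, self.scores_, self.explained_variance_ratio_ = fit_pca(X)
        self.features_ = pc_score_features(self.scores_, self.n_neurons_)
        return self

    def transform(self, X=None):
        return self.features_

    def cluster(self, reference_labels=None):
        out = cluster_pc_space(
            self.features_,
            ks=self.ks,
            seed=self.random_state,
            reference_labels=reference_labels,
        )
        if reference_labels is not None:
            self.assignments_, self.crosstabs_ = out
        else:
            self.assignments_ = out
        return self.assignments_
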