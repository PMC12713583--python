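"""Population state-space trajectories and choice-divergence time.

For one functional cluster, trial-averaged baseline-corrected spike density
functions for accept and reject choices (contralateral trials) are stacked
over time samples and decomposed with a single PCA (centered, unscaled).
Both conditions are projected onto the shared first three components, giving
two 3-D trajectories; the Euclidean distance between them is compared with a
baseline threshold — mean plus three SDs of the pre-target distance — and
the divergence time is the first post-target sample above threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .processing import AlignedActivity

# Window for the baseline distance statistics (mu_d, sigma_d).  The full
# 500-ms pre-target span (inside the fixation epoch) is used: the threshold is
# three SDs above the mean, and a shorter window estimates sigma_d from too
# few effectively independent samples of the smoothed process, inflating
# spurious threshold crossings.
BASELINE_DISTANCE_WINDOW_MS = (-500.0, 0.0)

__all__ = [
    "build_condition_matrices",
    "fit_trajectories",
    "divergence_time",
    "ChoiceTrajectories",
]


def build_condition_matrices(
    sdf: AlignedActivity,
    trials: pd.DataFrame,
    neuron_ids=None,
    baseline_ms: float = 500.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-averaged, baseline-corrected accept/reject matrices.

    Rows are neurons (optionally restricted to ``neuron_ids``, e.g. one
    cluster), columns time samples.  Baseline correction subtracts the mean
    pre-target activity of each condition-averaged row.  Neurons missing a
    choice class on contralateral trials are excluded from both matrices.
    Returns ``(accept, reject, kept_neuron_ids)``.
    """
    tinfo = trials.set_index("trial_id")
    base = (sdf.time_ms >= -baseline_ms) & (sdf.time_ms < 0)
    if not base.any():
        raise ValueError("baseline window outside the aligned axis")
    acc_rows, rej_rows, kept = [], [], []
    wanted = set(int(n) for n in neuron_ids) if neuron_ids is not None else None
    for i, nid in enumerate(sdf.neuron_ids):
        if wanted is not None and int(nid) not in wanted:
            continue
        tids = sdf.trial_ids[i]
        valid = tids >= 0
        tt = tinfo.loc[tids[valid]]
        vals = sdf.values[i, valid].astype(np.float64)
        contra = (tt["direction"] == "contra").to_numpy()
        accept = (tt["choice"] == "accept").to_numpy()
        a_sel, r_sel = contra & accept, contra & ~accept
        if not a_sel.any() or not r_sel.any():
            warnings.warn(f"neuron {nid} lacks a choice class; excluded", stacklevel=2)
            continue
        a = vals[a_sel].mean(axis=0)
        r = vals[r_sel].mean(axis=0)
        acc_rows.append(a - a[base].mean())
        rej_rows.append(r - r[base].mean())
        kept.append(int(nid))
    if not kept:
        raise ValueError("no neurons with both choice classes")
    return np.vstack(acc_rows), np.vstack(rej_rows), np.asarray(kept)


def fit_trajectories(
    accept: np.ndarray, reject: np.ndarray, n_components: int = 3
):
    """Shared-basis 3-D trajectories for the two conditions.

    PCA is fit on the vertical stack of both conditions' time samples
    (observations = time points, variables = neurons), centered but not
    scaled.  Returns ``(traj_accept, traj_reject, pca)`` with trajectories of
    shape (T, n_components).
    """
    accept = np.asarray(accept, dtype=float)
    reject = np.asarray(reject, dtype=float)
    if accept.shape != reject.shape:
        raise ValueError("condition matrices must share shape")
    n_neurons = accept.shape[0]
    k = min(n_components, n_neurons)
    if k < n_components:
        warnings.warn(
            f"only {n_neurons} neurons; using {k} components", stacklevel=2
        )
    stacked = np.concatenate([accept.T, reject.T], axis=0)  # 2T x N
    pca = PCA(n_components=k).fit(stacked)
    proj = pca.transform(stacked)
    T = accept.shape[1]
    return proj[:T], proj[T:], pca


def divergence_time(
    traj_accept: np.ndarray,
    traj_reject: np.ndarray,
    time_ms: np.ndarray,
    baseline_window_ms: tuple[float, float] = BASELINE_DISTANCE_WINDOW_MS,
    n_sd: float = 3.0,
):
    """First post-target time the inter-trajectory distance leaves baseline.

    Threshold: mean + ``n_sd`` x SD of the distance over the baseline window.
    Returns ``(divergence_ms_or_None, distance_series)``.  With a perfectly
    quiet baseline (zero mean and SD) any positive distance diverges at its
    first sample.
    """
    d = np.linalg.norm(np.asarray(traj_accept) - np.asarray(traj_reject), axis=1)
    t = np.asarray(time_ms, dtype=float)
    base = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
    if not base.any():
        raise ValueError("baseline window outside the time axis")
    thr = d[base].mean() + n_sd * d[base].std()
    post = np.flatnonzero((t >= 0) & (d > thr))
    return (float(t[post[0]]) if post.size else None), d


class ChoiceTrajectories(BaseEstimator):
    """Accept/reject trajectory model for one neuron population.

    Attributes
    ----------
    trajectory_accept_, trajectory_reject_ : (T, 3) PC-space paths
    distance_ : (T,) Euclidean distance series
    divergence_time_ms_ : float or None
    pca_ : fitted sklearn PCA
    neuron_ids_ : neurons contributing to the model
    """

    def __init__(
        self,
        n_components: int = 3,
        baseline_window_ms: tuple[float, float] = BASELINE_DISTANCE_WINDOW_MS,
        n_sd: float = 3.0,
    ):
        self.n_components = n_components
        self.baseline_window_ms = baseline_window_ms
        self.n_sd = n_sd

    def fit(self, sdf: AlignedActivity, trials, neuron_ids=None):
        acc, rej, kept = build_condition_matrices(sdf, trials, neuron_ids)
        self.neuron_ids_ = kept
        self.trajectory_accept_, self.trajectory_reject_, self.pca_ = fit_trajectories(
            acc, rej, self.n_components
        )
        self.time_ms_ = sdf.time_ms
        self.divergence_time_ms_, self.distance_ = divergence_time(
            self.trajectory_accept_,
            self.trajectory_reject_,
            sdf.time_ms,
            self.baseline_window_ms,
            self.n_sd,
        )
        return self
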