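"""Time-resolved single-neuron choice encoding.

At each position of a 50-ms window stepped in 1-ms increments, the per-trial
window-mean z activity is regressed on the upcoming choice coded accept = +1,
reject = -1:

    mean_activity = b0 + b_action * action + error

With this coding and balanced classes b_action is exactly half the
accept-minus-reject mean difference; unbalanced classes fall out of the same
least-squares solution.  Series are reported at window centers where the full
window fits, smoothed with a 21-ms moving average (nearest-edge padding, so
length is preserved) and sorted by response preference and latency for
heatmap display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator

from .processing import AlignedActivity

WINDOW_MS = 50
SMOOTH_MS = 21

__all__ = ["BetaSeries", "sliding_beta", "smooth_and_sort", "SlidingChoiceGLM"]


@dataclass
class BetaSeries:
    neuron_id: int
    center_ms: np.ndarray
    beta0: np.ndarray
    beta_action: np.ndarray


def _window_means(z: np.ndarray, window: int) -> np.ndarray:
    """Trial x position matrix of window means (positions where window fits)."""
    c = np.cumsum(np.concatenate([np.zeros((z.shape[0], 1)), z], axis=1), axis=1)
    return (c[:, window:] - c[:, :-window]) / window


def sliding_beta(
    z: np.ndarray,
    time_ms: np.ndarray,
    actions: np.ndarray,
    window_ms: int = WINDOW_MS,
    neuron_id: int = -1,
) -> BetaSeries:
    """OLS choice betas at every window position for one neuron.

    ``z`` is (trials x time) on a 1-ms grid, ``actions`` is +/-1 per trial.
    """
    z = np.asarray(z, dtype=float)
    a = np.asarray(actions, dtype=float)
    if set(np.unique(a)) - {1.0, -1.0}:
        raise ValueError("actions must be coded +1 (accept) / -1 (reject)")
    if (a > 0).all() or (a < 0).all():
        raise ValueError("both choice classes required")
    means = _window_means(z, int(window_ms))  # trials x positions
    abar = a.mean()
    ac = a - abar
    denom = float(ac @ ac)
    beta_action = (ac @ means) / denom
    beta0 = means.mean(axis=0) - beta_action * abar
    centers = time_ms[: means.shape[1]] + (window_ms - 1) / 2.0
    return BetaSeries(neuron_id, centers, beta0, beta_action)


def smooth_and_sort(
    series: list[BetaSeries],
    smooth_ms: int = SMOOTH_MS,
    latency_threshold_sd: float = 2.0,
):
    """Smoothed, heatmap-ordered matrix of action betas.

    Smoothing is a centered ``smooth_ms``-point moving average with
    nearest-edge padding.  Neurons are sorted by the sign of beta at the peak
    of |smoothed beta| (accept-preferring first), then by the first time
    |smoothed beta| exceeds ``latency_threshold_sd`` times the SD of the
    pre-target (t < 0) betas; all-zero series sort last.  Returns
    ``(matrix, order, center_ms)``.
    """
    if not series:
        raise ValueError("no beta series")
    centers = series[0].center_ms
    raw = np.vstack([s.beta_action for s in series])
    sm = uniform_filter1d(raw, size=int(smooth_ms), axis=1, mode="nearest")
    pre = centers < 0
    keys = []
    for i, s in enumerate(series):
        if not np.any(sm[i]):
            keys.append((2, np.inf, i))
            continue
        peak = np.argmax(np.abs(sm[i]))
        sign = 0 if sm[i, peak] > 0 else 1
        sd = raw[i, pre].std() if pre.any() else raw[i].std()
        thr = latency_threshold_sd * sd
        above = np.flatnonzero(np.abs(sm[i]) > thr)
        latency = centers[above[0]] if above.size else np.inf
        keys.append((sign, latency, i))
    order = np.array([k[2] for k in sorted(keys, key=lambda k: (k[0], k[1], k[2]))])
    return sm[order], order, centers


class SlidingChoiceGLM(BaseEstimator):
    """Population sliding-window choice regression, sklearn style.

    ``fit`` consumes target-aligned z activity plus the trial table and
    produces one BetaSeries per neuron with both choice classes present on
    contralateral trials (others skipped with a warning).

    Attributes
    ----------
    series_ : list of BetaSeries
    heatmap_ : ndarray (neurons x positions), smoothed and sorted
    order_ : permutation applied to ``series_`` for the heatmap
    center_ms_ : window-center time axis
    """

    def __init__(
        self,
        window_ms: int = WINDOW_MS,
        smooth_ms: int = SMOOTH_MS,
        reject_strategies: tuple[str, ...] = (
            "reject_return",
            "reject_stay",
            "reject_other",
        ),
    ):
        self.window_ms = window_ms
        self.smooth_ms = smooth_ms
        self.reject_strategies = reject_strategies

    def fit(self, aligned_z: AlignedActivity, trials):
        tinfo = trials.set_index("trial_id")
        self.series_ = []
        skipped = 0
        for i, nid in enumerate(aligned_z.neuron_ids):
            tids = aligned_z.trial_ids[i]
            valid = tids >= 0
            tt = tinfo.loc[tids[valid]]
            contra = (tt["direction"] == "contra").to_numpy()
            choice = tt["choice"].to_numpy()
            action = np.where(choice == "accept", 1.0, -1.0)
            keep = contra & (
                (choice == "accept") | np.isin(choice, self.reject_strategies)
            )
            z = aligned_z.values[i, valid][keep].astype(float)
            a = action[keep]
            if len(a) == 0 or (a > 0).all() or (a < 0).all():
                skipped += 1
                continue
            finite = np.isfinite(z).all(axis=1)
            self.series_.append(
                sliding_beta(
                    z[finite],
                    aligned_z.time_ms,
                    a[finite],
                    self.window_ms,
                    neuron_id=int(nid),
                )
            )
        if skipped:
            warnings.warn(
                f"{skipped} neurons skipped (one choice class absent)", stacklevel=2
            )
        self.heatmap_, self.order_, self.center_ms_ = smooth_and_sort(
            self.series_, self.smooth_ms
        )
        return self
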