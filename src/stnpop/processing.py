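"""Event alignment, spike-density estimation and baseline z-transformation.

Conventions: 1-ms bins, half-open ``[t, t+1)``; t = 0 at the alignment event;
Gaussian smoothing kernel (default sigma = 20 ms) truncated at +/-4 sigma with
zero padding at the edges (no mass renormalization, so the smoothed rate is
attenuated within ~4 sigma of the window edges); 500-ms pre-event baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

EVENT_COLUMNS = {
    "scene": "scene_on_ms",
    "target": "target_on_ms",
    "saccade": "saccade_on_ms",
}
BASELINE_MS = 500.0
DEFAULT_SIGMA_MS = 20.0

__all__ = [
    "AlignedActivity",
    "align_and_bin",
    "compute_sdf",
    "zscore",
    "epoch_mean",
    "baseline_rate",
    "aligned_zscored",
]


@dataclass
class AlignedActivity:
    """Neurons x trials x time grid of event-aligned activity.

    ``values[i, j]`` is the series for neuron ``neuron_ids[i]`` on trial
    ``trial_ids[i][j]`` (each neuron owns its session's trials, so the trial
    axis is ragged across neurons only in identity, not in length unless
    stated).  ``time_ms`` gives the left bin edges relative to the alignment
    event.  ``kind`` records the processing stage: "counts", "sdf" or "z".
    """

    values: np.ndarray                    # (n_neurons, n_trials, n_bins)
    time_ms: np.ndarray                   # (n_bins,)
    neuron_ids: np.ndarray                # (n_neurons,)
    trial_ids: np.ndarray                 # (n_neurons, n_trials) int, -1 = missing
    alignment: str
    kind: str = "counts"
    kernel_sigma_ms: float = DEFAULT_SIGMA_MS
    baseline_window_ms: float = BASELINE_MS
    excluded_neurons: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )

    def trial_mask(self) -> np.ndarray:
        return self.trial_ids >= 0

    def copy_with(self, values: np.ndarray, kind: str) -> "AlignedActivity":
        return AlignedActivity(
            values=values,
            time_ms=self.time_ms,
            neuron_ids=self.neuron_ids,
            trial_ids=self.trial_ids,
            alignment=self.alignment,
            kind=kind,
            kernel_sigma_ms=self.kernel_sigma_ms,
            baseline_window_ms=self.baseline_window_ms,
            excluded_neurons=self.excluded_neurons,
        )


def align_and_bin(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    event: str,
    window_ms: tuple[float, float],
) -> AlignedActivity:
    """Bin spike times into 1-ms half-open bins aligned to a trial event.

    Trials with a missing event time (e.g. "stay" trials have no saccade) are
    excluded with a logged warning.  Bin ``b`` covers
    ``[t0 + b, t0 + b + 1)`` ms relative to the event.
    """
    t0, t1 = float(window_ms[0]), float(window_ms[1])
    if t0 >= t1:
        raise ValueError(f"empty window {window_ms}")
    if event not in EVENT_COLUMNS:
        raise ValueError(f"unknown alignment event {event!r}")
    event_col = EVENT_COLUMNS[event]
    n_bins = int(round(t1 - t0))

    trials = trials.copy()
    missing = trials[event_col].isna()
    if missing.any():
        logger.warning(
            "%d trials excluded from %s alignment (missing event time)",
            int(missing.sum()),
            event,
        )
        trials = trials.loc[~missing]

    neuron_ids = np.sort(trials["neuron_id"].unique())
    if len(trials) == 0:
        return AlignedActivity(
            values=np.zeros((0, 0, n_bins), dtype=np.float32),
            time_ms=t0 + np.arange(n_bins, dtype=float),
            neuron_ids=neuron_ids.astype(np.int64),
            trial_ids=np.full((0, 0), -1, dtype=np.int64),
            alignment=event,
            kind="counts",
        )
    per_neuron = trials.groupby("neuron_id").size()
    max_trials = int(per_neuron.max())

    n_neurons = len(neuron_ids)
    values = np.zeros((n_neurons, max_trials, n_bins), dtype=np.float32)
    trial_ids = np.full((n_neurons, max_trials), -1, dtype=np.int64)

    # Map each trial to (neuron slot, trial slot) and the per-trial event
    # time, via dense arrays over the integer trial-id range.
    neuron_index = {int(n): i for i, n in enumerate(neuron_ids)}
    trials = trials.sort_values(["neuron_id", "trial_id"])
    slot_within = trials.groupby("neuron_id").cumcount().to_numpy()
    nidx = trials["neuron_id"].map(neuron_index).to_numpy()
    tid_arr = trials["trial_id"].to_numpy(dtype=np.int64)
    trial_ids[nidx, slot_within] = tid_arr

    max_id = int(tid_arr.max())
    event_of = np.full(max_id + 1, np.nan)
    event_of[tid_arr] = trials[event_col].to_numpy(dtype=float)
    slot_of = np.full(max_id + 1, -1, dtype=np.int64)
    slot_of[tid_arr] = nidx * max_trials + slot_within

    sp_tid = spikes["trial_id"].to_numpy(dtype=np.int64)
    sp_t = spikes["spike_time_ms"].to_numpy(dtype=float)
    inrange = (sp_tid >= 0) & (sp_tid <= max_id)
    sp_tid, sp_t = sp_tid[inrange], sp_t[inrange]
    known = slot_of[sp_tid] >= 0
    sp_tid, sp_t = sp_tid[known], sp_t[known]
    b = np.floor(sp_t - event_of[sp_tid] - t0).astype(np.int64)
    ok = (b >= 0) & (b < n_bins)
    np.add.at(values.reshape(-1, n_bins), (slot_of[sp_tid[ok]], b[ok]), 1.0)

    return AlignedActivity(
        values=values,
        time_ms=t0 + np.arange(n_bins, dtype=float),
        neuron_ids=neuron_ids,
        trial_ids=trial_ids,
        alignment=event,
        kind="counts",
    )


def _gaussian_kernel(sigma_ms: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete unit-sum Gaussian, truncated at ``truncate`` sigma."""
    r = int(truncate * sigma_ms + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_ms) ** 2)
    return k / k.sum()


def compute_sdf(counts, sigma_ms: float = DEFAULT_SIGMA_MS):
    """Spike density (spikes/s) from 1-ms counts via Gaussian smoothing.

    The kernel has unit area, is truncated at 4 sigma and the series is
    zero-padded, so the integral of the output over time equals the spike
    count up to edge truncation.  Accepts a raw array or an AlignedActivity.
    Large stacks are convolved with an FFT overlap-add path; small inputs use
    the direct path (both match ``gaussian_filter1d`` numerics).
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    if isinstance(counts, AlignedActivity):
        sdf = _smooth(counts.values, sigma_ms)
        out = counts.copy_with(sdf.astype(np.float32, copy=False), kind="sdf")
        out.kernel_sigma_ms = sigma_ms
        return out
    return _smooth(np.asarray(counts, dtype=float), sigma_ms)


def _smooth(arr: np.ndarray, sigma_ms: float) -> np.ndarray:
    if arr.size >= 1_000_000:
        import scipy.fft as sfft

        kernel = _gaussian_kernel(sigma_ms).astype(arr.dtype, copy=False)
        n = arr.shape[-1] + len(kernel) - 1
        nf = sfft.next_fast_len(n)
        out = sfft.irfft(
            sfft.rfft(arr, nf, axis=-1) * sfft.rfft(kernel, nf), nf, axis=-1
        )
        half = len(kernel) // 2
        return out[..., half : half + arr.shape[-1]] * 1000.0
    return (
        gaussian_filter1d(
            arr.astype(np.float64), sigma=sigma_ms, axis=-1, mode="constant",
            truncate=4.0,
        )
        * 1000.0
    )


def _baseline_slice(time_ms: np.ndarray, baseline_ms: float) -> np.ndarray:
    mask = (time_ms >= -baseline_ms) & (time_ms < 0)
    if not mask.any():
        raise ValueError("baseline window not inside the aligned window")
    return mask


def zscore(
    sdf: AlignedActivity,
    baseline_ms: float = BASELINE_MS,
    per_trial: bool = False,
) -> AlignedActivity:
    """Z-transform spike density against the pre-event baseline.

    By default the mean and SD are pooled per neuron over all trials and all
    baseline bins (stable for low-rate units); ``per_trial=True`` normalizes
    each trial by its own baseline statistics instead.  Neurons with zero
    baseline SD (silent or constant units) are flagged in
    ``excluded_neurons`` and their rows set to NaN.
    """
    base = _baseline_slice(sdf.time_ms, baseline_ms)
    vals = sdf.values  # float32 for large stacks; stats accumulate in float64
    mask = sdf.trial_mask()
    if per_trial:
        mu = vals[:, :, base].mean(axis=2, keepdims=True, dtype=np.float64)
        sd = vals[:, :, base].std(axis=2, keepdims=True, dtype=np.float64)
        bad = (sd[:, :, 0] == 0).any(axis=1) & mask.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (vals - mu) / sd
    else:
        # Pool baseline samples across this neuron's valid trials.  Invalid
        # trial slots hold all-zero series, so they add nothing to the moment
        # sums and only the sample count needs the mask.
        basevals = vals[:, :, base]
        n_samp = mask.sum(axis=1, dtype=np.float64) * int(base.sum())
        s1 = basevals.sum(axis=(1, 2), dtype=np.float64)
        s2 = np.square(basevals).sum(axis=(1, 2), dtype=np.float64)
        mu = s1 / n_samp
        sd = np.sqrt(np.maximum(s2 / n_samp - mu**2, 0.0))
        bad = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = (1.0 / np.where(sd == 0, np.nan, sd)).astype(vals.dtype)
            z = np.empty_like(vals)
            np.subtract(vals, mu.astype(vals.dtype)[:, None, None], out=z)
            z *= inv[:, None, None]
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} neurons with zero baseline SD excluded from z-scoring",
            stacklevel=2,
        )
        z[bad] = np.nan
    out = sdf.copy_with(z.astype(np.float32), kind="z")
    out.baseline_window_ms = baseline_ms
    out.excluded_neurons = sdf.neuron_ids[bad]
    return out


def epoch_mean(
    aligned: AlignedActivity, epoch_ms: tuple[float, float]
) -> np.ndarray:
    """Mean activity over bins in half-open ``[a, b)`` per (neuron, trial).

    Trial averaging within conditions is the caller's job; missing trials are
    NaN.  Raises on an empty epoch.
    """
    a, b = float(epoch_ms[0]), float(epoch_ms[1])
    mask = (aligned.time_ms >= a) & (aligned.time_ms < b)
    if not mask.any():
        raise ValueError(f"epoch {epoch_ms} outside the aligned time axis")
    out = aligned.values[:, :, mask].astype(np.float64).mean(axis=2)
    out[~aligned.trial_mask()] = np.nan
    return out


def baseline_rate(
    spikes: pd.DataFrame, trials: pd.DataFrame, baseline_ms: float = BASELINE_MS
) -> pd.Series:
    """Mean firing rate (Hz) in the pre-scene baseline, per neuron.

    Total spikes in the ``baseline_ms`` window before scene onset across all
    of the neuron's trials, divided by total baseline time.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    scene_on = pd.Series(
        trials["scene_on_ms"].to_numpy(), index=trials["trial_id"].to_numpy()
    )
    rel = spikes["spike_time_ms"].to_numpy() - scene_on.loc[spikes["trial_id"]].to_numpy()
    in_base = (rel >= -baseline_ms) & (rel < 0)
    counts = (
        spikes.loc[in_base].groupby("neuron_id").size()
        if in_base.any()
        else pd.Series(dtype=float)
    )
    n_trials = trials.groupby("neuron_id").size()
    rate = counts.reindex(n_trials.index, fill_value=0) / (
        n_trials * baseline_ms / 1000.0
    )
    rate.name = "baseline_rate_hz"
    return rate


def aligned_zscored(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    event: str,
    window_ms: tuple[float, float],
    sigma_ms: float = DEFAULT_SIGMA_MS,
    per_trial: bool = False,
) -> AlignedActivity:
    """Convenience composition: align -> bin -> SDF -> baseline z-score."""
    counts = align_and_bin(spikes, trials, event, window_ms)
    return zscore(compute_sdf(counts, sigma_ms), per_trial=per_trial)
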