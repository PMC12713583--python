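"""Synthetic spike-train and trial-table generator.

Emulates single-unit recordings from the subthalamic nucleus of two monkeys
performing a sequential accept/reject choice task.  Each simulated neuron
belongs to one of three planted response-profile clusters:

* cluster 1 — facilitative: firing increases for both good (rewarded) and bad
  (unrewarded) objects, more strongly for good;
* cluster 2 — value-coding bidirectional: firing increases for good objects
  and decreases for bad objects;
* cluster 3 — bad-preferring: firing increases for both, more strongly for bad.

Every neuron is recorded in its own session, so it owns a private block of
trials.  A trial presents a background scene (four scenes; scenes 3-4 reverse
the object-reward contingencies), then a good or bad object in the contra- or
ipsilateral hemifield.  Good objects are usually accepted with a saccade; bad
objects are rejected via a "return", "stay", or "other" strategy.  Firing is
an inhomogeneous Poisson process: a log-normal baseline plus a condition- and
cluster-specific linear ramp that starts at a per-trial onset latency and
plateaus 150 ms later.  On accept trials the saccadic reaction time is planted
as ``RT = a + b * latency + noise`` so that downstream latency/RT regressions
have a recoverable ground truth; reject reaction times are shifted slower and
wider.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SpikeDataset",
    "simulate_dataset",
    "sample_condition_rate",
    "make_divergence_matrices",
    "make_leakage_features",
    "SCENE_ON_MS",
    "FIX_ON_MS",
    "TARGET_ON_MS",
    "TRIAL_START_MS",
    "TRIAL_END_MS",
    "RAMP_MS",
]

# Trial clock (ms): scene onset at 0, central fixation at 1000, object (target)
# onset at 1700 -- a 1000-ms scene epoch followed by a 700-ms fixation epoch.
SCENE_ON_MS = 0.0
FIX_ON_MS = 1000.0
TARGET_ON_MS = 1700.0
# Spikes are simulated from 600 ms before scene onset (pre-scene baseline plus
# smoothing margin) to 800 ms after target onset.
TRIAL_START_MS = -600.0
TRIAL_END_MS = 2500.0
# Linear response ramp duration from onset latency to plateau.
RAMP_MS = 150.0

_VALUES = ("good", "bad")
_DIRECTIONS = ("contra", "ipsi")
_SCENES = (1, 2, 3, 4)
_FLEXIBLE_SCENES = frozenset({3, 4})
_STRATEGIES = ("reject_return", "reject_stay", "reject_other")


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


def _default_gain() -> np.ndarray:
    # [cluster, value(good, bad), direction(contra, ipsi)] in Hz.
    return np.array(
        [
            [[18.0, 7.2], [8.0, 3.2]],     # cluster 1: good > bad, both up
            [[14.0, 5.6], [-10.0, -4.0]],  # cluster 2: good up, bad down
            [[4.0, 1.6], [16.0, 6.4]],     # cluster 3: bad > good
        ]
    )


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated recording campaign.

    Parameters
    ----------
    n_neurons_per_cluster
        Neurons planted in each of the three response-profile clusters.
    n_trials_per_condition
        Trials per (scene, value, direction) cell per neuron; 4*2*2 cells.
    baseline_log_mean, baseline_log_sd
        Log-normal baseline firing-rate distribution (median ``exp(log_mean)``
        Hz; default median 20 Hz).
    response_gain_hz
        Array ``(3, 2, 2)`` of plateau rate changes, indexed by
        [cluster, (good, bad), (contra, ipsi)].
    onset_latency_mean_ms, onset_latency_sd_ms
        Per-cluster mean and common SD of the per-trial response-onset
        latency relative to target onset.
    rt_intercept_ms, rt_slope, rt_sd_ms
        Accept-trial reaction-time model RT = a + b*latency + N(0, sd).
    reject_rt_shift_ms, reject_rt_sd_ms
        Reject ("return"/"other") reaction times use the same linear mean
        shifted slower by ``reject_rt_shift_ms`` with a wider noise SD.
    p_accept_good_stable, p_accept_good_flexible
        Probability of accepting a good object in stable (scenes 1-2) and
        flexible (scenes 3-4) scenes; otherwise the trial is a return-reject.
    reject_probs_stable, reject_probs_flexible
        (return, stay, other) strategy probabilities for bad objects.
    kernel_sigma_ms
        Gaussian smoothing bandwidth carried as metadata for downstream
        spike-density estimation.
    seed
        Master seed; per-neuron streams are spawned deterministically.
    """

    n_neurons_per_cluster: tuple[int, int, int] = (50, 50, 50)
    n_trials_per_condition: int = 20
    baseline_log_mean: float = float(np.log(20.0))
    baseline_log_sd: float = 0.3
    response_gain_hz: np.ndarray = field(default_factory=_default_gain)
    onset_latency_mean_ms: tuple[float, float, float] = (100.0, 90.0, 120.0)
    onset_latency_sd_ms: float = 10.0
    rt_intercept_ms: float = 130.0
    rt_slope: float = 0.5
    rt_sd_ms: float = 30.0
    reject_rt_shift_ms: float = 80.0
    reject_rt_sd_ms: float = 45.0
    p_accept_good_stable: float = 0.95
    p_accept_good_flexible: float = 0.90
    reject_probs_stable: tuple[float, float, float] = (0.70, 0.20, 0.10)
    reject_probs_flexible: tuple[float, float, float] = (0.60, 0.25, 0.15)
    kernel_sigma_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.response_gain_hz = np.asarray(self.response_gain_hz, dtype=float)
        self.validate()

    def validate(self) -> None:
        counts = tuple(self.n_neurons_per_cluster)
        if len(counts) != 3 or any((int(c) != c or c < 0) for c in counts):
            raise ConfigurationError(
                "n_neurons_per_cluster must be 3 non-negative integers"
            )
        if self.n_trials_per_condition < 2:
            raise ConfigurationError("n_trials_per_condition must be >= 2")
        if self.response_gain_hz.shape != (3, 2, 2):
            raise ConfigurationError("response_gain_hz must have shape (3, 2, 2)")
        for p in (self.p_accept_good_stable, self.p_accept_good_flexible):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"accept probability {p} outside [0, 1]")
        for probs in (self.reject_probs_stable, self.reject_probs_flexible):
            arr = np.asarray(probs, dtype=float)
            if arr.shape != (3,) or (arr < 0).any() or (arr > 1).any():
                raise ConfigurationError(f"strategy probabilities {probs} invalid")
            if not np.isclose(arr.sum(), 1.0):
                raise ConfigurationError(
                    f"strategy probabilities {probs} must sum to 1"
                )
        if self.onset_latency_sd_ms < 0 or self.rt_sd_ms <= 0:
            raise ConfigurationError("latency SD must be >= 0 and RT SD > 0")
        if self.kernel_sigma_ms <= 0:
            raise ConfigurationError("kernel_sigma_ms must be positive")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted parameters for parameter-recovery tests."""

    neurons: pd.DataFrame          # neuron_id, monkey_id, true_cluster, baseline_rate_hz
    onset_latencies: pd.DataFrame  # neuron_id, trial_id, true_onset_latency_ms
    true_rt_slope: float
    true_divergence_time_ms: dict[int, float]  # cluster label -> onset mean


@dataclass
class SpikeDataset:
    """Long-format spike table plus neuron metadata.

    ``spikes`` columns: neuron_id, trial_id, spike_time_ms (trial clock, ms,
    sorted ascending within each trial).  ``neurons`` columns: neuron_id,
    monkey_id.
    """

    spikes: pd.DataFrame
    neurons: pd.DataFrame


def _ramp01(t: np.ndarray | float) -> np.ndarray | float:
    """Unit ramp: 0 before 0, linear to 1 over RAMP_MS, 1 after."""
    return np.clip(np.asarray(t, dtype=float) / RAMP_MS, 0.0, 1.0)


def sample_condition_rate(
    cluster: int,
    value: str,
    direction: str,
    t: np.ndarray | float,
    config: SimulationConfig,
    *,
    baseline_hz: float | None = None,
    latency_ms: float | None = None,
):
    """Deterministic firing-rate function at time ``t`` (ms after target onset).

    Baseline before the onset latency, baseline + gain * ramp afterwards,
    rectified at zero.  ``baseline_hz`` defaults to the configured log-normal
    median; ``latency_ms`` defaults to the cluster's mean onset latency.
    """
    if cluster not in (1, 2, 3):
        raise ValueError(f"unknown cluster label {cluster!r}")
    if value not in _VALUES or direction not in _DIRECTIONS:
        raise ValueError(f"unknown condition ({value!r}, {direction!r})")
    if baseline_hz is None:
        baseline_hz = float(np.exp(config.baseline_log_mean))
    if latency_ms is None:
        latency_ms = config.onset_latency_mean_ms[cluster - 1]
    gain = config.response_gain_hz[
        cluster - 1, _VALUES.index(value), _DIRECTIONS.index(direction)
    ]
    rate = baseline_hz + gain * _ramp01(np.asarray(t, dtype=float) - latency_ms)
    return np.maximum(rate, 0.0)


def _condition_grid(n_per_cond: int):
    """Flat per-trial condition arrays for one session (fixed order)."""
    scene, value_idx, dir_idx = np.meshgrid(
        np.asarray(_SCENES),
        np.arange(2),
        np.arange(2),
        indexing="ij",
    )
    scene = np.repeat(scene.ravel(), n_per_cond)
    value_idx = np.repeat(value_idx.ravel(), n_per_cond)
    dir_idx = np.repeat(dir_idx.ravel(), n_per_cond)
    return scene, value_idx, dir_idx


def _simulate_trials_for_neuron(
    rng: np.random.Generator, config: SimulationConfig, cluster: int
) -> dict[str, np.ndarray]:
    """One session's trial variables as flat arrays (no ids attached)."""
    scene, value_idx, dir_idx = _condition_grid(config.n_trials_per_condition)
    n = len(scene)
    flexible = np.isin(scene, list(_FLEXIBLE_SCENES))

    # Per-trial onset latency for this neuron's cluster.
    lat_mean = config.onset_latency_mean_ms[cluster - 1]
    lat = rng.normal(lat_mean, config.onset_latency_sd_ms, n)
    lat = np.maximum(lat, 30.0)  # physiological floor

    # Choice: good objects accepted with scene-dependent probability, else
    # rejected by return; bad objects rejected via one of three strategies.
    good = value_idx == 0
    p_acc = np.where(
        flexible, config.p_accept_good_flexible, config.p_accept_good_stable
    )
    u = rng.random(n)
    choice_code = np.empty(n, dtype=np.int64)  # 0 accept, 1 return, 2 stay, 3 other
    choice_code[good] = np.where(u[good] < p_acc[good], 0, 1)
    cum_stable = np.cumsum(config.reject_probs_stable)
    cum_flex = np.cumsum(config.reject_probs_flexible)
    bad = ~good
    strat = np.where(
        flexible[bad],
        np.searchsorted(cum_flex, u[bad], side="left"),
        np.searchsorted(cum_stable, u[bad], side="left"),
    )
    choice_code[bad] = np.minimum(strat, 2) + 1

    # Reaction times: planted linear dependence on onset latency for accepts;
    # shifted slower and wider for rejects; absent for "stay".
    mean_rt = config.rt_intercept_ms + config.rt_slope * lat
    rt = np.full(n, np.nan)
    acc = choice_code == 0
    rt[acc] = mean_rt[acc] + rng.normal(0.0, config.rt_sd_ms, int(acc.sum()))
    rej_moving = (choice_code == 1) | (choice_code == 3)
    rt[rej_moving] = (
        mean_rt[rej_moving]
        + config.reject_rt_shift_ms
        + rng.normal(0.0, config.reject_rt_sd_ms, int(rej_moving.sum()))
    )
    rt = np.where(np.isnan(rt), np.nan, np.maximum(rt, 60.0))
    return {
        "scene": scene,
        "value_idx": value_idx,
        "dir_idx": dir_idx,
        "onset_latency_ms": lat,
        "choice_code": choice_code,
        "rt_ms": rt,
    }


def _simulate_spikes_for_neuron(
    rng: np.random.Generator,
    config: SimulationConfig,
    cluster: int,
    baseline_hz: float,
    trials: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Thinning sampler: returns (trial_index, spike_time_ms) flat arrays."""
    n_trials = len(trials["scene"])
    gains = config.response_gain_hz[
        cluster - 1, trials["value_idx"], trials["dir_idx"]
    ]
    latencies = trials["onset_latency_ms"]

    duration_s = (TRIAL_END_MS - TRIAL_START_MS) / 1000.0
    rate_max = baseline_hz + max(float(config.response_gain_hz[cluster - 1].max()), 0.0)
    rate_max = max(rate_max, 1e-9)
    counts = rng.poisson(rate_max * duration_s, n_trials)
    trial_idx = np.repeat(np.arange(n_trials), counts)
    times = rng.uniform(TRIAL_START_MS, TRIAL_END_MS, counts.sum())

    # Instantaneous rate at each candidate spike.
    rel = times - TARGET_ON_MS - latencies[trial_idx]
    rate = baseline_hz + gains[trial_idx] * _ramp01(rel)
    rate = np.maximum(rate, 0.0)
    keep = rng.random(times.size) * rate_max < rate
    trial_idx, times = trial_idx[keep], times[keep]
    order = np.lexsort((times, trial_idx))
    return trial_idx[order], times[order]


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[SpikeDataset, pd.DataFrame, GroundTruth]:
    """Simulate a full recording campaign.

    Returns ``(SpikeDataset, TrialTable, GroundTruth)``.  The trial table is
    long format with one row per (neuron's session, trial); trial ids are
    globally unique and the ``neuron_id`` column records the session owner.
    Bit-reproducible for a fixed config/seed.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    if seed is not None:
        config = config.replace(seed=seed)

    ss = np.random.SeedSequence(config.seed)
    n_total = int(sum(config.n_neurons_per_cluster))
    child_seeds = ss.spawn(n_total + 1)
    master = np.random.default_rng(child_seeds[0])

    clusters = np.repeat([1, 2, 3], config.n_neurons_per_cluster)
    baselines = np.exp(
        master.normal(config.baseline_log_mean, config.baseline_log_sd, n_total)
    )
    monkeys = np.where(np.arange(n_total) % 2 == 0, "C", "S")

    spike_neuron, spike_trial, spike_time = [], [], []
    trial_parts: dict[str, list[np.ndarray]] = {
        k: []
        for k in (
            "trial_id", "neuron_id", "scene", "value_idx", "dir_idx",
            "choice_code", "rt_ms", "onset_latency_ms",
        )
    }
    trial_offset = 0
    for i in range(n_total):
        rng = np.random.default_rng(child_seeds[i + 1])
        cluster = int(clusters[i])
        trials = _simulate_trials_for_neuron(rng, config, cluster)
        n_tr = len(trials["scene"])
        trial_ids = trial_offset + np.arange(n_tr)
        trial_offset += n_tr
        ti, st = _simulate_spikes_for_neuron(
            rng, config, cluster, float(baselines[i]), trials
        )
        spike_neuron.append(np.full(len(st), i))
        spike_trial.append(trial_ids[ti])
        spike_time.append(st)
        trial_parts["trial_id"].append(trial_ids)
        trial_parts["neuron_id"].append(np.full(n_tr, i))
        for k in ("scene", "value_idx", "dir_idx", "choice_code", "rt_ms",
                  "onset_latency_ms"):
            trial_parts[k].append(trials[k])

    cat = {k: np.concatenate(v) for k, v in trial_parts.items()}
    choice_names = np.array(["accept", *_STRATEGIES])
    trial_table = pd.DataFrame(
        {
            "trial_id": cat["trial_id"],
            "neuron_id": cat["neuron_id"],
            "monkey_id": monkeys[cat["neuron_id"]],
            "scene": cat["scene"],
            "value": np.asarray(_VALUES)[cat["value_idx"]],
            "direction": np.asarray(_DIRECTIONS)[cat["dir_idx"]],
            "choice": choice_names[cat["choice_code"]],
            "rt_ms": cat["rt_ms"],
            "scene_on_ms": SCENE_ON_MS,
            "target_on_ms": TARGET_ON_MS,
            "saccade_on_ms": TARGET_ON_MS + cat["rt_ms"],
        }
    )

    neurons = pd.DataFrame(
        {
            "neuron_id": np.arange(n_total),
            "monkey_id": monkeys,
            "true_cluster": clusters,
            "baseline_rate_hz": baselines,
        }
    )
    dataset = SpikeDataset(
        spikes=pd.DataFrame(
            {
                "neuron_id": np.concatenate(spike_neuron),
                "trial_id": np.concatenate(spike_trial),
                "spike_time_ms": np.concatenate(spike_time),
            }
        ),
        neurons=neurons[["neuron_id", "monkey_id"]].copy(),
    )
    truth = GroundTruth(
        neurons=neurons,
        onset_latencies=pd.DataFrame(
            {
                "neuron_id": cat["neuron_id"],
                "trial_id": cat["trial_id"],
                "true_onset_latency_ms": cat["onset_latency_ms"],
            }
        ),
        true_rt_slope=config.rt_slope,
        true_divergence_time_ms={
            k: config.onset_latency_mean_ms[k - 1] for k in (1, 2, 3)
        },
    )
    return dataset, trial_table, truth


def make_divergence_matrices(
    t0_ms: float,
    seed: int = 0,
    n_neurons: int = 20,
    n_trials: int = 40,
    accept_gain_hz: tuple[float, float] = (42.0, 6.0),
    reject_gain_hz: tuple[float, float] = (-30.0, 6.0),
    baseline_hz: float = 20.0,
    window_ms: tuple[float, float] = (-580.0, 380.0),
    identical: bool = False,
):
    """Synthetic condition matrices with a choice separation planted at t0.

    Recovery harness for the trajectory-divergence statistic: both condition
    matrices share the same stationary noise model (trial-averaged smoothed
    Poisson baseline activity, true-mean corrected, so zero-mean without an
    empirical centering step), and the accept/reject difference is a linear
    ramp added in the smoothed-rate domain starting exactly at ``t0_ms``.
    Planting after smoothing keeps the separation onset sharp: smoothing an
    onset in the spike domain spreads it acausally by the kernel width, which
    would make the planted time ill-defined.  ``identical=True`` returns the
    same matrix twice (no-separation control).  Returns
    ``(accept, reject, time_ms)``.
    """
    rng = np.random.default_rng(seed)
    from .processing import compute_sdf  # local import; processing is noise model

    time_ms = np.arange(window_ms[0], window_ms[1])
    ramp = np.clip((time_ms - t0_ms) / RAMP_MS, 0.0, 1.0)
    gains = [
        rng.normal(*accept_gain_hz, n_neurons),
        rng.normal(*reject_gain_hz, n_neurons),
    ]
    mats = []
    for g in gains:
        counts = rng.poisson(
            baseline_hz / 1000.0, (n_neurons, n_trials, len(time_ms))
        )
        noise = compute_sdf(counts.astype(np.float32)).mean(axis=1) - baseline_hz
        mats.append(noise + g[:, None] * ramp[None, :])
        if identical:
            return mats[0], mats[0].copy(), time_ms
    return mats[0], mats[1], time_ms


def make_leakage_features(
    n_neurons: int = 30,
    n_trials: int = 40,
    n_bins: int = 600,
    rate_range_hz: tuple[float, float] = (0.0, 300.0),
    accept_prob_range: tuple[float, float] = (0.02, 0.98),
    seed: int = 0,
):
    """Feature table where labels are independent of activity given the neuron.

    Each neuron gets an idiosyncratic temporal rate profile (a fixed random
    rate per bin, constant across its trials) and an idiosyncratic accept
    probability, but conditional on the neuron the choice label carries no
    information about the spike counts.  The distinct mean profiles make
    neuron identity linearly decodable, so a decoder evaluated with folds
    split at the trial level can learn each training neuron's majority label
    (leakage) while folds grouped by neuron cannot.  Returns
    ``(X, y, groups)``.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.uniform(*rate_range_hz, (n_neurons, n_bins))
    p_acc = rng.uniform(*accept_prob_range, n_neurons)
    X = rng.poisson(
        np.repeat(profiles, n_trials, axis=0) / 1000.0,
        (n_neurons * n_trials, n_bins),
    ).astype(float)
    y = (rng.random(n_neurons * n_trials) < np.repeat(p_acc, n_trials)).astype(int)
    groups = np.repeat(np.arange(n_neurons), n_trials)
    return X, y, groups
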