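import numpy as np
import pytest

from stnpop.processing import align_and_bin, aligned_zscored, compute_sdf
from stnpop.simulate import SimulationConfig, simulate_dataset

WINDOW = (-580.0, 380.0)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured simulated campaign (12 neurons)."""
    cfg = SimulationConfig(
        n_neurons_per_cluster=(4, 4, 4), n_trials_per_condition=6, seed=7
    )
    dataset, trials, truth = simulate_dataset(cfg)
    return cfg, dataset, trials, truth


@pytest.fixture(scope="session")
def small_aligned_z(small_sim):
    _, dataset, trials, _ = small_sim
    return aligned_zscored(dataset.spikes, trials, "target", WINDOW)


@pytest.fixture(scope="session")
def small_sdf(small_sim):
    _, dataset, trials, _ = small_sim
    return compute_sdf(align_and_bin(dataset.spikes, trials, "target", WINDOW))


@pytest.fixture(scope="session")
def default_features():
    """Window features of a mid-sized default-profile population."""
    from stnpop.clustering import build_features

    cfg = SimulationConfig(
        n_neurons_per_cluster=(15, 15, 15), n_trials_per_condition=10, seed=11
    )
    dataset, trials, truth = simulate_dataset(cfg)
    az = aligned_zscored(dataset.spikes, trials, "target", WINDOW)
    feats = build_features(az, trials)
    true_labels = (
        truth.neurons.set_index("neuron_id")["true_cluster"].reindex(feats.index)
    )
    return feats, true_labels.to_numpy()


def brute_force_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """O(N^2) reference silhouette, written independently of sklearn."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(
            D[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return float(s.mean())
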