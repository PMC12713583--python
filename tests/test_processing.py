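"""Binning, smoothing and z-transform contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stnpop.processing import (
    AlignedActivity,
    align_and_bin,
    baseline_rate,
    compute_sdf,
    epoch_mean,
    zscore,
)


def _tiny_tables(spike_times, event=100.0):
    spikes = pd.DataFrame(
        {"neuron_id": 0, "trial_id": 0, "spike_time_ms": np.sort(spike_times)}
    )
    trials = pd.DataFrame(
        {
            "trial_id": [0],
            "neuron_id": [0],
            "monkey_id": ["C"],
            "scene": [1],
            "value": ["good"],
            "direction": ["contra"],
            "choice": ["accept"],
            "rt_ms": [200.0],
            "scene_on_ms": [event - 1700.0],
            "target_on_ms": [event],
            "saccade_on_ms": [event + 200.0],
        }
    )
    return spikes, trials


class TestAlignAndBin:
    def test_empty_window_is_zero(self):
        spikes, trials = _tiny_tables([5000.0])
        out = align_and_bin(spikes, trials, "target", (0.0, 10.0))
        assert out.values.sum() == 0

    def test_half_open_convention(self):
        # Spike exactly at t0 lands in the first bin; one at t1 is excluded.
        spikes, trials = _tiny_tables([100.0, 110.0])
        out = align_and_bin(spikes, trials, "target", (0.0, 10.0))
        assert out.values[0, 0, 0] == 1
        assert out.values.sum() == 1

    def test_missing_event_trial_excluded(self):
        spikes, trials = _tiny_tables([100.0])
        trials.loc[0, "saccade_on_ms"] = np.nan
        out = align_and_bin(spikes, trials, "saccade", (0.0, 10.0))
        assert out.values.shape[0] == 0 or (out.trial_ids < 0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-400, 400), min_size=0, max_size=60),
           st.integers(0, 1000))
    def test_counts_match_brute_force(self, times, seed):
        rng = np.random.default_rng(seed)
        t0 = float(rng.integers(-200, 0))
        t1 = t0 + float(rng.integers(10, 300))
        event = 1700.0
        spikes, trials = _tiny_tables(np.asarray(times) + event, event=event)
        out = align_and_bin(spikes, trials, "target", (t0, t1))
        rel = np.asarray(times)
        expect = int(((rel >= t0) & (rel < t1)).sum())
        assert out.values.sum() == expect

    def test_unknown_event_raises(self):
        spikes, trials = _tiny_tables([0.0])
        with pytest.raises(ValueError):
            align_and_bin(spikes, trials, "cue", (0.0, 10.0))


class TestComputeSdf:
    def test_zero_counts_zero_sdf(self):
        assert np.all(compute_sdf(np.zeros(300)) == 0)

    def test_single_spike_conserves_unit_mass(self):
        counts = np.zeros(500)
        counts[250] = 1
        sdf = compute_sdf(counts, 20.0)
        # integral over ms of spikes/s equals 1 spike x 1000
        assert sdf.sum() == pytest.approx(1000.0, rel=1e-6)
        assert np.argmax(sdf) == 250

    def test_constant_rate_interior(self):
        counts = np.full(1000, 0.05)  # 50 Hz expressed as expected counts
        sdf = compute_sdf(counts, 20.0)
        assert np.allclose(sdf[200:800], 50.0, atol=1e-9)

    def test_mass_conserved_for_random_trains(self):
        # spikes kept 4 sigma away from the window edges lose no kernel mass
        rng = np.random.default_rng(0)
        counts = np.zeros(800)
        counts[80:720] = rng.poisson(0.05, 640)
        sdf = compute_sdf(counts, 20.0)
        assert sdf.sum() / 1000.0 == pytest.approx(counts.sum(), rel=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            compute_sdf(np.zeros(10), 0.0)

    def test_fft_path_matches_direct_path(self):
        rng = np.random.default_rng(1)
        small = rng.poisson(0.05, (3, 4, 700)).astype(np.float32)
        big = np.tile(small, (20, 5, 1))  # crosses the FFT-path threshold
        ref = compute_sdf(small.astype(float))
        out = compute_sdf(big.astype(float))
        assert np.allclose(out[:3, :4], ref, atol=1e-7)


class TestZscore:
    def _aligned(self, values):
        values = np.asarray(values, dtype=np.float32)
        n_bins = values.shape[-1]
        return AlignedActivity(
            values=values,
            time_ms=np.arange(-500.0, n_bins - 500.0),
            neuron_ids=np.arange(values.shape[0]),
            trial_ids=np.zeros((values.shape[0], values.shape[1]), dtype=int),
            alignment="target",
            kind="sdf",
        )

    def test_constant_equal_to_baseline_is_flagged(self):
        # constant series has zero baseline SD -> excluded, not z = 0/0
        a = self._aligned(np.full((1, 2, 600), 5.0))
        with pytest.warns(UserWarning):
            z = zscore(a)
        assert 0 in z.excluded_neurons
        assert np.isnan(z.values).all()

    def test_definition_hand_computed(self):
        # baseline mean 5, SD 2 -> a bin at 9 maps to z = 2
        base = np.tile([3.0, 7.0], 250)  # exactly mean 5, SD 2
        series = np.concatenate([base, [9.0] * 100])
        z = zscore(self._aligned(series[None, None, :]))
        assert z.values[0, 0, -1] == pytest.approx(2.0, abs=1e-5)
        assert z.values[0, 0, :500].mean() == pytest.approx(0.0, abs=1e-5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        series = rng.poisson(5, (2, 3, 700)).astype(float)
        z1 = zscore(self._aligned(series))
        z2 = zscore(self._aligned(3.5 * series + 11.0))
        assert np.allclose(z1.values, z2.values, atol=1e-4)

    def test_per_trial_mode_centers_each_trial(self):
        rng = np.random.default_rng(3)
        series = rng.poisson(5, (1, 4, 700)).astype(float)
        z = zscore(self._aligned(series), per_trial=True)
        base = z.values[0, :, :500]
        assert np.allclose(base.mean(axis=1), 0.0, atol=1e-5)


class TestEpochMean:
    def _aligned_z(self, values):
        values = np.asarray(values, dtype=np.float32)
        return AlignedActivity(
            values=values,
            time_ms=np.arange(0.0, values.shape[-1]),
            neuron_ids=np.arange(values.shape[0]),
            trial_ids=np.zeros((values.shape[0], values.shape[1]), dtype=int),
            alignment="target",
            kind="z",
        )

    def test_constant(self):
        a = self._aligned_z(np.full((1, 1, 400), 3.25))
        assert epoch_mean(a, (100, 300))[0, 0] == pytest.approx(3.25)

    def test_linear_ramp_closed_form(self):
        t = np.arange(400.0)
        a = self._aligned_z((t / 100.0)[None, None, :])
        # mean of 100..299 over 100 = 199.5/100
        assert epoch_mean(a, (100, 300))[0, 0] == pytest.approx(1.995, abs=1e-5)

    def test_symmetric_ramp_zero(self):
        t = np.linspace(-1, 1, 200)
        a = self._aligned_z(t[None, None, :])
        assert epoch_mean(a, (0, 200))[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_empty_epoch_raises(self):
        a = self._aligned_z(np.zeros((1, 1, 100)))
        with pytest.raises(ValueError):
            epoch_mean(a, (500, 600))


class TestBaselineRate:
    def test_hand_computed(self):
        # 10 spikes across 20 trials x 0.5 s baseline -> 1 Hz
        trials = pd.DataFrame(
            {
                "trial_id": np.arange(20),
                "neuron_id": 0,
                "scene_on_ms": 0.0,
            }
        )
        spikes = pd.DataFrame(
            {
                "neuron_id": 0,
                "trial_id": np.arange(10) % 20,
                "spike_time_ms": -250.0,
            }
        )
        assert baseline_rate(spikes, trials)[0] == pytest.approx(1.0)

    def test_zero_spikes(self):
        trials = pd.DataFrame(
            {"trial_id": [0], "neuron_id": [0], "scene_on_ms": [0.0]}
        )
        spikes = pd.DataFrame(
            {"neuron_id": [0], "trial_id": [0], "spike_time_ms": [100.0]}
        )
        assert baseline_rate(spikes, trials)[0] == 0.0

    def test_poisson_rate_recovered(self, small_sim):
        cfg, ds, trials, truth = small_sim
        rates = baseline_rate(ds.spikes, trials)
        planted = truth.neurons.set_index("neuron_id")["baseline_rate_hz"]
        n_tr = trials.groupby("neuron_id").size()
        for nid in rates.index:
            se = np.sqrt(planted[nid] / (0.5 * n_tr[nid]))
            assert abs(rates[nid] - planted[nid]) < 4 * se
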