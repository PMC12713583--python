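"""Mixed-effects condition/RT models, response parameters, behavior tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from stnpop.encoding import (
    behavior_tests,
    bonferroni_threshold,
    build_condition_table,
    extract_response_params,
    fit_activity_lmm,
    fit_rt_lmm,
    parametric_bootstrap_test,
    posthoc_pairwise,
)
from stnpop.mixedlm import MixedLM


def _rt_frame(seed, b=0.5, n_mk=2, n_per=6, n_tr=10, sd_neuron=10.0, sd_res=30.0):
    rng = np.random.default_rng(seed)
    monkey = np.repeat(np.arange(n_mk), n_per * n_tr)
    neuron = np.repeat(np.arange(n_mk * n_per), n_tr)
    lat = rng.normal(100, 10, len(neuron))
    rt = (
        130.0 + b * lat
        + rng.normal(0, 5, n_mk)[monkey]
        + rng.normal(0, sd_neuron, n_mk * n_per)[neuron]
        + rng.normal(0, sd_res, len(neuron))
    )
    return pd.DataFrame(
        {"monkey_id": monkey, "neuron_id": neuron, "rt_ms": rt,
         "onset_latency_ms": lat}
    )


class TestMixedLM:
    def test_matches_statsmodels_single_factor(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(0)
        g = np.repeat(np.arange(10), 8)
        x = rng.normal(size=80)
        y = 1.0 + 2.0 * x + rng.normal(0, 1, 10)[g] + rng.normal(0, 1, 80)
        ours = MixedLM(np.column_stack([np.ones(80), x]), y, [g]).fit()
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        ref = smf.mixedlm("y ~ x", df, groups=df.g).fit(reml=True)
        assert ours.beta == pytest.approx(ref.params[:2].to_numpy(), abs=1e-3)
        assert ours.se == pytest.approx(ref.bse[:2].to_numpy(), abs=1e-3)
        assert ours.sigma2 == pytest.approx(ref.scale, rel=1e-2)
        assert ours.var_components[0] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=5e-2, abs=1e-2
        )

    def test_balanced_one_way_closed_form(self):
        # REML variance components of the balanced random-intercept model
        # equal the ANOVA moment estimators when both are interior.
        rng = np.random.default_rng(1)
        m, r = 12, 6
        g = np.repeat(np.arange(m), r)
        y = rng.normal(0, 2.0, m)[g] + rng.normal(0, 1.0, m * r)
        fit = MixedLM(np.ones((m * r, 1)), y, [g]).fit()
        gm = y.reshape(m, r).mean(axis=1)
        msa = r * ((gm - gm.mean()) ** 2).sum() / (m - 1)
        mse = ((y.reshape(m, r) - gm[:, None]) ** 2).sum() / (m * (r - 1))
        assert fit.sigma2 == pytest.approx(mse, rel=1e-4)
        assert fit.var_components[0] == pytest.approx((msa - mse) / r, rel=1e-3)

    def test_degenerate_zero_variance_matches_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 3.0 - 1.5 * x + rng.normal(0, 0.5, 60)
        g = rng.integers(0, 6, 60)  # grouping unrelated to y
        X = np.column_stack([np.ones(60), x])
        fit = MixedLM(X, y, [g]).fit()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        # variance ratio sits at the boundary (numerically ~0)
        assert fit.beta == pytest.approx(ols, abs=1e-2)
        assert fit.var_components[0] < 0.1 * fit.sigma2


class TestActivityLmm:
    @staticmethod
    def _cond_frame(seed, value_effect=0.0, sd_neuron=0.5, sd_res=0.3):
        rng = np.random.default_rng(seed)
        rows = []
        u_mk = rng.normal(0, 0.1, 2)
        u_nr = rng.normal(0, sd_neuron, 2 * 10)
        for mk in range(2):
            for nr in range(10):
                nid = mk * 10 + nr
                for scene in (1, 2, 3, 4):
                    for vi, value in enumerate(("good", "bad")):
                        for direction in ("contra", "ipsi"):
                            mu = value_effect * (vi == 0)
                            rows.append(
                                (f"M{mk}", nid, scene, value, direction, "tgt",
                                 mu + u_mk[mk] + u_nr[nid]
                                 + rng.normal(0, sd_res))
                            )
        return pd.DataFrame(
            rows,
            columns=["monkey_id", "neuron_id", "scene", "value", "direction",
                     "epoch", "activity"],
        )

    def test_variance_component_recovery(self):
        ests = []
        for seed in range(15):
            fit = fit_activity_lmm(self._cond_frame(seed))
            ests.append(fit.full.var_components[-1])
        assert np.mean(ests) == pytest.approx(0.25, rel=0.25)

    def test_value_effect_estimated(self):
        fit = fit_activity_lmm(self._cond_frame(0, value_effect=1.0))
        terms = fit.fixed_effects.set_index("term")
        # treatment coding with 'bad' as reference: value[good] main effect
        est = terms.loc["value[good]", "estimate"]
        assert est == pytest.approx(1.0, abs=0.3)

    def test_bootstrap_null_p_not_extreme(self):
        fit = fit_activity_lmm(self._cond_frame(3))
        p = parametric_bootstrap_test(fit, n_boot=99, seed=0)
        assert 1.0 / 100.0 <= p <= 1.0

    def test_bootstrap_detects_planted_effect(self):
        fit = fit_activity_lmm(self._cond_frame(4, value_effect=1.5))
        p = parametric_bootstrap_test(fit, n_boot=99, seed=0)
        assert p == pytest.approx(1.0 / 100.0)


class TestPosthoc:
    def test_identical_means_not_significant(self):
        table = TestActivityLmm._cond_frame(5)
        out = posthoc_pairwise(table)
        assert (out["p_adj"] > 0.05).mean() > 0.9

    def test_shifted_condition_flagged(self):
        table = TestActivityLmm._cond_frame(6)
        sel = (table.value == "good") & (table.direction == "contra")
        table.loc[sel, "activity"] += 5.0
        out = posthoc_pairwise(table)
        hit = out[(out.cond_a == "contra good") | (out.cond_b == "contra good")]
        rest = out[~((out.cond_a == "contra good") | (out.cond_b == "contra good"))]
        assert (hit["p_adj"] < 0.05).all()
        assert (rest["p_adj"] > 0.05).all()

    def test_adjustment_capped_at_one(self):
        table = TestActivityLmm._cond_frame(7)
        out = posthoc_pairwise(table)
        assert (out["p_adj"] <= 1.0).all()
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()


class TestResponseParams:
    def test_linear_ramp_closed_form(self):
        t = np.arange(-100.0, 300.0)
        z = np.clip(t, 0, 200) / 50.0  # 0 -> 4 over 0..200 ms
        p = extract_response_params(z, t, search_end_ms=250.0)
        assert p["onset_latency_ms"] == 101.0  # first bin with z > 2
        assert p["peak_magnitude_z"] == pytest.approx(z[t == 250.0][0])
        # slope of the underlying ramp is 1/50 z per ms
        assert p["slope_z_per_ms"] == pytest.approx(0.02, rel=1e-6)

    def test_no_response_flagged(self):
        t = np.arange(-100.0, 300.0)
        assert extract_response_params(np.full_like(t, 1.5), t, 300.0) is None

    def test_step_function(self):
        t = np.arange(-100.0, 300.0)
        z = np.where(t >= 80, 3.0, 0.0)
        p = extract_response_params(z, t, search_end_ms=300.0)
        assert p["onset_latency_ms"] == 80.0
        assert p["peak_magnitude_z"] == 3.0
        assert p["slope_z_per_ms"] == 0.0  # peak in the onset bin


class TestRtLmm:
    def test_slope_recovery_small_batch(self):
        betas = [fit_rt_lmm(_rt_frame(s), "onset_latency_ms")["beta"]
                 for s in range(20)]
        # Monte-Carlo SE of the mean over 20 sims is ~0.06
        assert np.mean(betas) == pytest.approx(0.5, abs=0.15)

    def test_constant_predictor_rejected(self):
        df = _rt_frame(0)
        df["onset_latency_ms"] = 100.0
        with pytest.raises(ValueError):
            fit_rt_lmm(df, "onset_latency_ms")

    def test_too_few_neurons_rejected(self):
        df = _rt_frame(0).query("neuron_id == 0")
        with pytest.raises(ValueError):
            fit_rt_lmm(df, "onset_latency_ms")


class TestBonferroni:
    def test_reported_family(self):
        assert bonferroni_threshold(0.05, 9) == pytest.approx(0.05 / 9)
        assert round(bonferroni_threshold(0.05, 9), 4) == 0.0056

    def test_identity_and_arithmetic(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 5) == pytest.approx(0.002)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)


class TestBehavior:
    def test_generator_pattern_detected(self):
        from stnpop.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n_neurons_per_cluster=(3, 3, 3),
                               n_trials_per_condition=12, seed=13)
        _, trials, _ = simulate_dataset(cfg)
        out = behavior_tests(trials)
        assert out["welch_p"] < 1e-4
        assert out["accept_mean_rt"] < out["reject_mean_rt"]

    def test_welch_null_calibrated(self):
        rng = np.random.default_rng(0)
        rej = 0
        n_sims = 400
        for _ in range(n_sims):
            t, p = stats.ttest_ind(rng.normal(size=30), rng.normal(size=40),
                                   equal_var=False)
            rej += p < 0.05
        assert stats.binomtest(rej, n_sims, 0.05).pvalue > 0.001

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[10, 0], [0, 10]])
        _, p = stats.fisher_exact(table)
        # two-sided: both extreme tables, each with prob 1/C(20,10)
        assert p == pytest.approx(2.0 / comb(20, 10, exact=True), rel=1e-12)

    def test_stay_proportion_contrast(self):
        from stnpop.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_neurons_per_cluster=(4, 4, 4), n_trials_per_condition=20,
            reject_probs_stable=(0.85, 0.05, 0.10),
            reject_probs_flexible=(0.45, 0.45, 0.10), seed=17,
        )
        _, trials, _ = simulate_dataset(cfg)
        out = behavior_tests(trials)
        assert out["fisher_p"] < 1e-6


class TestConditionTable:
    def test_constant_z_constant_rows(self, small_aligned_z, small_sim):
        _, _, trials, _ = small_sim
        const = small_aligned_z.copy_with(
            np.full_like(small_aligned_z.values, 2.5), kind="z"
        )
        table = build_condition_table(const, trials, (100.0, 300.0))
        assert np.allclose(table["activity"], 2.5)

    def test_planted_value_preference(self, small_aligned_z, small_sim):
        _, _, trials, truth = small_sim
        table = build_condition_table(small_aligned_z, trials, (100.0, 300.0))
        tc = truth.neurons.set_index("neuron_id")["true_cluster"]
        t1 = table[table.neuron_id.map(tc) == 1]
        contra = t1[t1.direction == "contra"]
        good = contra[contra.value == "good"]["activity"].mean()
        bad = contra[contra.value == "bad"]["activity"].mean()
        assert good > bad
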