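"""End-to-end pipeline: simulate (or ingest) -> process -> analyze -> report.

Stages run in dependency order; a stage failure halts its dependents,
completes independents, and is recorded in the report.  All stage outputs are
figure-ready CSV/JSON files under the output directory, and the fully
resolved configuration (including seeds) is serialized into the report for
provenance.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clustering, decoding, encoding, io, pca_validation
from .processing import aligned_zscored, baseline_rate, compute_sdf, align_and_bin
from .simulate import SimulationConfig, simulate_dataset
from .sliding_glm import SlidingChoiceGLM
from .trajectories import ChoiceTrajectories

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "input": {"spikes": None, "trials": None, "simulate": True},
    "simulate": {"n_neurons_per_cluster": [8, 8, 8], "n_trials_per_condition": 6},
    "stages": {
        "clustering": True,
        "pca_validation": True,
        "encoding": True,
        "sliding_glm": True,
        "trajectories": True,
        "decoding": True,
    },
    "clustering": {"n_repeats": 100, "k_range": [2, 6]},
    "encoding": {"epoch_ms": [100, 300], "n_boot": 199},
    "decoding": {"k_outer": 4, "k_inner": 3, "n_lambdas": 6, "max_iter": 200},
    "window_ms": [-600, 600],
}


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def run_pipeline(config: dict, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config,
        "stages": {},
        "warnings": [],
    }
    t_start = time.time()
    seed = int(config["seed"])

    def record(stage, ok, summary=None, error=None):
        report["stages"][stage] = {
            "ok": ok,
            "summary": summary,
            "error": error,
        }

    # -- data -----------------------------------------------------------------
    if config["input"].get("simulate", True):
        sim_cfg = SimulationConfig(
            n_neurons_per_cluster=tuple(config["simulate"]["n_neurons_per_cluster"]),
            n_trials_per_condition=int(config["simulate"]["n_trials_per_condition"]),
            seed=seed,
        )
        dataset, trials, truth = simulate_dataset(sim_cfg)
        io.write_spikes(dataset.spikes, outdir / "spikes.csv")
        io.write_trials(trials, outdir / "trials.csv")
        truth.neurons.to_csv(outdir / "ground_truth_neurons.csv", index=False)
        record("simulate", True, {"n_neurons": len(dataset.neurons), "n_trials": len(trials)})
    else:
        dataset_spikes = io.read_spikes(config["input"]["spikes"])
        trials = io.read_trials(config["input"]["trials"])
        from .simulate import SpikeDataset

        dataset = SpikeDataset(
            spikes=dataset_spikes,
            neurons=trials[["neuron_id", "monkey_id"]].drop_duplicates(),
        )
        truth = None
        record("ingest", True, {"n_trials": len(trials)})

    window = tuple(config["window_ms"])
    aligned_z = aligned_zscored(dataset.spikes, trials, "target", window)
    rates = baseline_rate(dataset.spikes, trials)

    stages = config["stages"]
    labels_by_neuron = None

    # -- clustering -----------------------------------------------------------
    if stages.get("clustering", True):
        try:
            feats = clustering.build_features(aligned_z, trials)
            model = clustering.ResponseProfileClusterer(
                k_range=tuple(config["clustering"]["k_range"]),
                n_repeats=int(config["clustering"]["n_repeats"]),
                random_state=seed,
            ).fit(feats)
            assign = pd.DataFrame(
                {"neuron_id": feats.index, "cluster": model.labels_}
            )
            assign.to_csv(outdir / "cluster_assignments.csv", index=False)
            model.silhouette_by_k_.to_csv(outdir / "silhouette_by_k.csv", index=False)
            labels_by_neuron = assign.set_index("neuron_id")["cluster"]
            h, p = clustering.compare_baseline_rates(
                rates.loc[feats.index], model.labels_
            )
            record(
                "clustering", True,
                {"chosen_k": model.k_, "sizes": np.bincount(model.labels_)[1:].tolist(),
                 "baseline_kruskal_h": h, "baseline_kruskal_p": p},
            )
        except Exception as e:  # recorded, not raised
            logger.exception("clustering failed")
            record("clustering", False, error=str(e))

    # -- PCA validation -------------------------------------------------------
    if stages.get("pca_validation", True):
        try:
            mat, kept = pca_validation.build_stacked_matrix(aligned_z, trials)
            spca = pca_validation.StackedConditionPCA(random_state=seed).fit(mat)
            ref = (
                labels_by_neuron.loc[kept].to_numpy()
                if labels_by_neuron is not None
                else None
            )
            spca.cluster(reference_labels=ref)
            pd.DataFrame(
                {"component": np.arange(1, len(spca.explained_variance_ratio_) + 1),
                 "explained_variance_ratio": spca.explained_variance_ratio_}
            ).to_csv(outdir / "pca_scree.csv", index=False)
            record(
                "pca_validation", True,
                {"var_pc1_3": float(spca.explained_variance_ratio_[:3].sum()),
                 "n_neurons": int(spca.n_neurons_)},
            )
        except Exception as e:
            logger.exception("pca_validation failed")
            record("pca_validation", False, error=str(e))

    # -- encoding stats -------------------------------------------------------
    if stages.get("encoding", True):
        try:
            epoch = tuple(config["encoding"]["epoch_ms"])
            cond = encoding.build_condition_table(aligned_z, trials, epoch)
            fit = encoding.fit_activity_lmm(cond)
            encoding.parametric_bootstrap_test(
                fit, n_boot=int(config["encoding"]["n_boot"]), seed=seed
            )
            fit.fixed_effects.to_csv(outdir / "activity_lmm.csv", index=False)
            posthoc = encoding.posthoc_pairwise(cond)
            posthoc.to_csv(outdir / "posthoc_contrasts.csv", index=False)
            beh = encoding.behavior_tests(trials)
            rt_results = []
            if truth is not None and labels_by_neuron is not None:
                params = encoding.extract_response_params_dataset(aligned_z, trials)
                if len(params):
                    params["cluster"] = labels_by_neuron.reindex(
                        params["neuron_id"]
                    ).to_numpy()
                    for cl, sub in params.groupby("cluster"):
                        for par in (
                            "onset_latency_ms", "peak_magnitude_z", "slope_z_per_ms",
                        ):
                            try:
                                r = encoding.fit_rt_lmm(sub, par)
                                r["cluster"] = cl
                                rt_results.append(r)
                            except ValueError as e:
                                report["warnings"].append(
                                    f"rt_lmm cluster {cl} {par}: {e}"
                                )
            if rt_results:
                pd.DataFrame(rt_results).to_csv(outdir / "rt_lmm.csv", index=False)
            record(
                "encoding", True,
                {"bootstrap_p": fit.bootstrap_p,
                 "welch_p": beh["welch_p"], "fisher_p": beh["fisher_p"],
                 "n_rt_models": len(rt_results),
                 "rt_threshold": encoding.bonferroni_threshold(0.05, 9)},
            )
        except Exception as e:
            logger.exception("encoding failed")
            record("encoding", False, error=str(e))

    # -- sliding GLM ----------------------------------------------------------
    if stages.get("sliding_glm", True):
        try:
            glm = SlidingChoiceGLM().fit(aligned_z, trials)
            pd.DataFrame(
                glm.heatmap_, columns=[f"{t:.1f}" for t in glm.center_ms_]
            ).to_csv(outdir / "sliding_beta.csv", index=False)
            record("sliding_glm", True, {"n_neurons": len(glm.series_)})
        except Exception as e:
            logger.exception("sliding_glm failed")
            record("sliding_glm", False, error=str(e))

    # -- trajectories ---------------------------------------------------------
    if stages.get("trajectories", True):
        try:
            counts = align_and_bin(dataset.spikes, trials, "target", window)
            sdf = compute_sdf(counts)
            out = {}
            groups = (
                labels_by_neuron.groupby(labels_by_neuron).groups
                if labels_by_neuron is not None
                else {0: aligned_z.neuron_ids}
            )
            dist_frames = []
            for cl, nids in groups.items():
                tr = ChoiceTrajectories().fit(sdf, trials, neuron_ids=list(nids))
                out[int(cl)] = tr.divergence_time_ms_
                dist_frames.append(
                    pd.DataFrame(
                        {"cluster": int(cl), "time_ms": sdf.time_ms,
                         "distance": tr.distance_}
                    )
                )
            pd.concat(dist_frames).to_csv(outdir / "trajectory_distance.csv", index=False)
            record("trajectories", True, {"divergence_ms": out})
        except Exception as e:
            logger.exception("trajectories failed")
            record("trajectories", False, error=str(e))

    # -- decoding -------------------------------------------------------------
    if stages.get("decoding", True):
        try:
            cluster_map = (
                labels_by_neuron.to_dict()
                if labels_by_neuron is not None
                else {int(n): 0 for n in aligned_z.neuron_ids}
            )
            table = decoding.build_feature_table(
                dataset.spikes, trials, cluster_map, tuple(config["window_ms"])
            )
            io.write_feature_table(table, outdir / "features")
            dec = decoding.GroupedElasticNetDecoder(
                k_outer=int(config["decoding"]["k_outer"]),
                k_inner=int(config["decoding"]["k_inner"]),
                n_lambdas=int(config["decoding"]["n_lambdas"]),
                max_iter=int(config["decoding"]["max_iter"]),
                random_state=seed,
            ).fit(table)
            summary = {"auc": dec.score_}
            if labels_by_neuron is not None and len(set(cluster_map.values())) > 1:
                abl = dec.ablation()
                abl.to_csv(outdir / "decoding_ablation.csv", index=False)
                summary["ablation"] = abl.to_dict("records")
            record("decoding", True, summary)
        except Exception as e:
            logger.exception("decoding failed")
            record("decoding", False, error=str(e))

    report["wall_clock_s"] = time.time() - t_start
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
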