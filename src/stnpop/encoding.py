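"""Condition and trial-by-trial encoding statistics.

Four analysis families:

* condition LMMs — epoch-mean normalized activity modeled as
  ``activity ~ scene * value * direction + (1|monkey) + (1|monkey:neuron)``,
  with whole-model significance from a parametric bootstrap against the
  random-effects-only null and Bonferroni-corrected post-hoc contrasts;
* trial response parameters — onset latency (first bin with z > 2 after
  target onset), peak magnitude (max z within 150 ms of onset) and slope
  (peak minus onset z over elapsed time);
* reaction-time LMMs — ``rt ~ parameter + (1|monkey) + (1|monkey:neuron)``
  per cluster and parameter with Satterthwaite P-values, judged against the
  Bonferroni threshold 0.05 / 9;
* behavioral tests — Welch t-test on accept vs reject reaction times and
  Fisher's exact test on stay proportions in stable vs flexible scenes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import MixedLM, MixedLMResult, parametric_bootstrap
from .processing import AlignedActivity, epoch_mean

logger = logging.getLogger(__name__)

ONSET_Z_THRESHOLD = 2.0
PEAK_WINDOW_MS = 150.0

__all__ = [
    "build_condition_table",
    "fit_activity_lmm",
    "parametric_bootstrap_test",
    "posthoc_pairwise",
    "extract_response_params",
    "extract_response_params_dataset",
    "fit_rt_lmm",
    "bonferroni_threshold",
    "behavior_tests",
    "ActivityLmmFit",
]


def build_condition_table(
    aligned_z: AlignedActivity,
    trials: pd.DataFrame,
    epoch_ms: tuple[float, float],
    epoch_label: str = "target",
) -> pd.DataFrame:
    """Epoch-mean z per neuron x scene x value x direction.

    Rows with no valid trials in a cell are omitted (logged).
    """
    em = epoch_mean(aligned_z, epoch_ms)
    tinfo = trials.set_index("trial_id")
    records = []
    n_missing = 0
    for i, nid in enumerate(aligned_z.neuron_ids):
        tids = aligned_z.trial_ids[i]
        valid = tids >= 0
        tt = tinfo.loc[tids[valid]]
        vals = em[i, valid]
        monkey = tt["monkey_id"].iloc[0] if "monkey_id" in tt else "M"
        for (scene, value, direction), grp in tt.groupby(
            ["scene", "value", "direction"], observed=True
        ):
            sel = tt.index.isin(grp.index)
            cell = vals[np.asarray(sel)]
            cell = cell[np.isfinite(cell)]
            if len(cell) == 0:
                n_missing += 1
                continue
            records.append(
                (monkey, nid, scene, value, direction, epoch_label, cell.mean())
            )
    if n_missing:
        logger.warning("%d neuron x condition cells omitted (no trials)", n_missing)
    return pd.DataFrame(
        records,
        columns=[
            "monkey_id", "neuron_id", "scene", "value", "direction",
            "epoch", "activity",
        ],
    )


def _factorial_design(
    table: pd.DataFrame, factors: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design with all interactions (intercept first)."""
    main = {}
    for f in factors:
        levels = sorted(table[f].unique())
        for lev in levels[1:]:
            main[f"{f}[{lev}]"] = (table[f] == lev).to_numpy(dtype=float)
    cols = {"Intercept": np.ones(len(table))}
    names_by_factor = {
        f: [n for n in main if n.startswith(f"{f}[")] for f in factors
    }
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            for terms in itertools.product(*(names_by_factor[f] for f in combo)):
                name = ":".join(terms)
                col = np.ones(len(table))
                for t in terms:
                    col = col * main[t]
                cols[name] = col
    return np.column_stack(list(cols.values())), list(cols.keys())


@dataclass
class ActivityLmmFit:
    """Full condition-model fit plus its random-effects-only null."""

    full: MixedLMResult
    null: MixedLMResult
    term_names: list[str]
    fixed_effects: pd.DataFrame   # estimate, se, df, t, p (Satterthwaite)
    singular: bool
    bootstrap_p: float | None = None
    posthoc: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def _grouping(table: pd.DataFrame) -> list[np.ndarray]:
    monkey = table["monkey_id"].to_numpy()
    neuron = (
        table["monkey_id"].astype(str) + ":" + table["neuron_id"].astype(str)
    ).to_numpy()
    if len(np.unique(monkey)) < 2:
        # A single monkey makes the monkey intercept unidentifiable.
        return [neuron]
    return [monkey, neuron]


def fit_activity_lmm(
    table: pd.DataFrame,
    factors: tuple[str, ...] = ("scene", "value", "direction"),
) -> ActivityLmmFit:
    """REML fit of the full factorial condition model.

    Random intercepts for monkey and neuron-within-monkey; with only two
    monkeys the monkey variance is weakly identified and boundary fits are
    flagged, not hidden.
    """
    X, names = _factorial_design(table, factors)
    y = table["activity"].to_numpy(dtype=float)
    groups = _grouping(table)
    full = MixedLM(X, y, groups).fit(reml=True)
    null = MixedLM(np.ones((len(y), 1)), y, groups).fit(reml=True)
    sat = full.satterthwaite()
    fixed = pd.DataFrame(
        {
            "term": names,
            "estimate": sat["estimate"],
            "se": sat["se"],
            "df": sat["df"],
            "t": sat["t"],
            "p": sat["p"],
        }
    )
    fit = ActivityLmmFit(
        full=full,
        null=null,
        term_names=names,
        fixed_effects=fixed,
        singular=full.singular,
    )
    if full.singular:
        fit.warnings.append("variance ratio at boundary (singular fit)")
    return fit


def parametric_bootstrap_test(
    fit: ActivityLmmFit, n_boot: int = 10_000, seed: int = 0
) -> float:
    """Whole-model p: parametric-bootstrap LR of full vs random-effects null."""
    p, lr, _, failures = parametric_bootstrap(fit.full, fit.null, n_boot, seed)
    if failures:
        logger.warning("%d bootstrap refits failed", failures)
    fit.bootstrap_p = p
    return p


def posthoc_pairwise(
    table: pd.DataFrame, family_size: int = 6
) -> pd.DataFrame:
    """Pairwise condition contrasts within each scene, Bonferroni-corrected.

    The four cells (value x direction) are compared with paired t-tests
    across neurons; the correction family is the 6 contrasts within a scene.
    Contrasts with a missing condition are omitted.
    """
    conds = [("good", "contra"), ("bad", "contra"), ("good", "ipsi"), ("bad", "ipsi")]
    rows = []
    for scene, sub in table.groupby("scene"):
        wide = sub.pivot_table(
            index="neuron_id", columns=["value", "direction"], values="activity"
        )
        for (v1, d1), (v2, d2) in itertools.combinations(conds, 2):
            if (v1, d1) not in wide.columns or (v2, d2) not in wide.columns:
                continue
            paired = wide[[(v1, d1), (v2, d2)]].dropna()
            a, b = paired[(v1, d1)], paired[(v2, d2)]
            if len(paired) < 2 or np.allclose(a - b, (a - b).iloc[0]):
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_rel(a, b)
            rows.append(
                {
                    "scene": scene,
                    "cond_a": f"{d1} {v1}",
                    "cond_b": f"{d2} {v2}",
                    "mean_diff": float((a - b).mean()),
                    "t": float(t),
                    "p_raw": float(p),
                    "p_adj": float(min(1.0, family_size * p))
                    if np.isfinite(p)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def extract_response_params(
    z_series: np.ndarray,
    time_ms: np.ndarray,
    search_end_ms: float,
    threshold: float = ONSET_Z_THRESHOLD,
    peak_window_ms: float = PEAK_WINDOW_MS,
) -> dict | None:
    """Onset latency, peak magnitude and slope of a single-trial z series.

    Onset is the first bin strictly exceeding ``threshold`` between target
    onset (t = 0) and ``search_end_ms``; the peak is the maximum z within
    ``peak_window_ms`` after onset; the slope is (peak - z(onset)) over the
    elapsed time, zero when the peak falls in the onset bin.  Returns None
    when the threshold is never exceeded ("no response").
    """
    z = np.asarray(z_series, dtype=float)
    t = np.asarray(time_ms, dtype=float)
    search = (t >= 0) & (t < search_end_ms) & np.isfinite(z)
    idx = np.flatnonzero(search & (z > threshold))
    if idx.size == 0:
        return None
    i0 = idx[0]
    onset = t[i0]
    win = (t >= onset) & (t < onset + peak_window_ms) & np.isfinite(z)
    j = np.flatnonzero(win)[np.argmax(z[win])]
    peak, t_peak = z[j], t[j]
    slope = 0.0 if t_peak == onset else (peak - z[i0]) / (t_peak - onset)
    return {
        "onset_latency_ms": float(onset),
        "peak_magnitude_z": float(peak),
        "slope_z_per_ms": float(slope),
    }


def extract_response_params_dataset(
    aligned_z: AlignedActivity,
    trials: pd.DataFrame,
    max_latency_ms: float | None = None,
) -> pd.DataFrame:
    """Response parameters for every accept / contralateral-good trial.

    The onset search window runs from target onset to the trial's saccade
    (the response must precede the action); trials without a supra-threshold
    response are dropped with a logged count.
    """
    tinfo = trials.set_index("trial_id")
    rows = []
    n_no_response = 0
    for i, nid in enumerate(aligned_z.neuron_ids):
        tids = aligned_z.trial_ids[i]
        for j, tid in enumerate(tids):
            if tid < 0:
                continue
            tr = tinfo.loc[tid]
            if (
                tr["choice"] != "accept"
                or tr["value"] != "good"
                or tr["direction"] != "contra"
            ):
                continue
            rt = float(tr["rt_ms"])
            end = rt if max_latency_ms is None else min(rt, max_latency_ms)
            params = extract_response_params(
                aligned_z.values[i, j], aligned_z.time_ms, search_end_ms=end
            )
            if params is None:
                n_no_response += 1
                continue
            rows.append(
                {
                    "monkey_id": tr.get("monkey_id", "M"),
                    "neuron_id": nid,
                    "trial_id": tid,
                    "rt_ms": rt,
                    **params,
                }
            )
    if n_no_response:
        logger.info("%d trials without supra-threshold response", n_no_response)
    return pd.DataFrame(rows)


def fit_rt_lmm(params: pd.DataFrame, parameter: str):
    """``rt ~ parameter + (1|monkey) + (1|monkey:neuron)``, Satterthwaite p.

    Returns a dict with the unstandardized slope ``beta``, its SE,
    Satterthwaite df, p-value, a CI, and the singularity flag.
    """
    usable = params.groupby("neuron_id").size()
    if (usable >= 2).sum() < 2:
        raise ValueError("need >= 2 neurons with >= 2 usable trials")
    x = params[parameter].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate predictor {parameter!r} (constant)")
    X = np.column_stack([np.ones_like(x), x])
    y = params["rt_ms"].to_numpy(dtype=float)
    res = MixedLM(X, y, _grouping(params)).fit(reml=True)
    sat = res.satterthwaite(np.array([0.0, 1.0]))
    ci_half = stats.t.ppf(0.975, sat["df"]) * sat["se"]
    return {
        "parameter": parameter,
        "beta": float(sat["estimate"]),
        "se": float(sat["se"]),
        "df": float(sat["df"]),
        "p": float(sat["p"]),
        "ci_low": float(sat["estimate"] - ci_half),
        "ci_high": float(sat["estimate"] + ci_half),
        "singular": res.singular,
        "n_trials": int(len(params)),
    }


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m (exact; display-rounding is the caller's)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def behavior_tests(trials: pd.DataFrame) -> dict:
    """Welch t-test on accept vs return-reject RTs; Fisher on stay proportions.

    The Fisher table counts stay vs non-stay responses to bad objects in
    stable (scenes 1-2) versus flexible (scenes 3-4) scenes.
    """
    acc = trials.loc[trials["choice"] == "accept", "rt_ms"].dropna()
    rej = trials.loc[trials["choice"] == "reject_return", "rt_ms"].dropna()
    if len(acc) < 2 or len(rej) < 2:
        raise ValueError("both RT groups must be non-empty")
    if acc.std(ddof=1) == 0 or rej.std(ddof=1) == 0:
        raise ValueError("zero-variance RT group")
    t, p = stats.ttest_ind(acc, rej, equal_var=False)
    # Welch-Satterthwaite df.
    va, vr = acc.var(ddof=1) / len(acc), rej.var(ddof=1) / len(rej)
    df = (va + vr) ** 2 / (va**2 / (len(acc) - 1) + vr**2 / (len(rej) - 1))

    bad = trials[trials["value"] == "bad"]
    stable = bad["scene"].isin([1, 2])
    stay = bad["choice"] == "reject_stay"
    table = np.array(
        [
            [int((stable & stay).sum()), int((stable & ~stay).sum())],
            [int((~stable & stay).sum()), int((~stable & ~stay).sum())],
        ]
    )
    odds, fisher_p = stats.fisher_exact(table)
    return {
        "welch_t": float(t),
        "welch_df": float(df),
        "welch_p": float(p),
        "accept_mean_rt": float(acc.mean()),
        "reject_mean_rt": float(rej.mean()),
        "fisher_table": table,
        "fisher_odds": float(odds),
        "fisher_p": float(fisher_p),
    }
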