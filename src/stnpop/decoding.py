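"""Population choice and reaction-time decoding with Elastic Net.

Samples are (neuron, trial) pairs: each sample's features are one neuron's
spike counts in 1-ms bins from 600 ms before to 600 ms after target onset
(1200 features), its label the trial's choice (accept/reject) or reaction
time.  Because repeated trials from one neuron are not independent, folds —
outer and inner — are grouped by neuron: all of a neuron's samples share a
fold.  Within each outer training set, features are standardized on training
data only and an inner grouped cross-validation selects the regularization
strength lambda (mixing parameter alpha fixed at 0.5) maximizing AUC
(choice, logistic loss) or minimizing MSE (reaction time, squared loss); a
model refit at the selected lambda predicts the held-out fold.  Performance
is the AUC (or R^2) of the pooled out-of-fold predictions.  Cluster
contributions are probed by ablation (drop one cluster) and single-cluster
decoding; significance by permutation of labels within neuron, repeating the
entire nested procedure.

The lambda grid follows the glmnet convention: ``n_lambdas`` values
log-spaced over ``lambda_decades`` decades down from lambda_max, the smallest
penalty that zeroes every coefficient.  For the logistic path,
``C = 1 / (n * lambda)`` maps the grid onto scikit-learn's parameterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

from .processing import align_and_bin

logger = logging.getLogger(__name__)

DECODING_WINDOW_MS = (-600.0, 600.0)

__all__ = [
    "FeatureTable",
    "build_feature_table",
    "grouped_folds",
    "GroupedElasticNetDecoder",
    "nested_cv_elastic_net",
    "ablation_and_single_cluster",
    "permutation_test",
]


@dataclass
class FeatureTable:
    """Samples x binned-count features with labels, groups and clusters."""

    X: np.ndarray              # (n_samples, n_bins) float
    choice: np.ndarray         # 1 = accept, 0 = reject
    rt_ms: np.ndarray          # NaN where undefined
    groups: np.ndarray         # neuron id per sample
    clusters: np.ndarray       # cluster label per sample
    time_ms: np.ndarray

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.X[mask], self.choice[mask], self.rt_ms[mask],
            self.groups[mask], self.clusters[mask], self.time_ms,
        )


def build_feature_table(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    cluster_of_neuron: dict | pd.Series,
    window_ms: tuple[float, float] = DECODING_WINDOW_MS,
    pseudo_population: bool = False,
) -> FeatureTable:
    """Binned-count feature table on contralateral trials.

    One sample per (neuron, trial); reject samples pool all three reject
    strategies.  ``pseudo_population=True`` instead aligns the k-th
    accept/reject trial across neurons and concatenates their bins into one
    wide sample (sensitivity mode; groups are then trial ranks).
    """
    contra = trials[trials["direction"] == "contra"]
    counts = align_and_bin(spikes, contra, "target", window_ms)
    tinfo = contra.set_index("trial_id")
    X_rows, choice, rt, groups, clusters = [], [], [], [], []
    for i, nid in enumerate(counts.neuron_ids):
        tids = counts.trial_ids[i]
        valid = np.flatnonzero(tids >= 0)
        for j in valid:
            tr = tinfo.loc[tids[j]]
            X_rows.append(counts.values[i, j])
            choice.append(1 if tr["choice"] == "accept" else 0)
            rt.append(tr["rt_ms"] if np.isfinite(tr["rt_ms"]) else np.nan)
            groups.append(int(nid))
            clusters.append(cluster_of_neuron[int(nid)])
    table = FeatureTable(
        X=np.asarray(X_rows, dtype=float),
        choice=np.asarray(choice, dtype=int),
        rt_ms=np.asarray(rt, dtype=float),
        groups=np.asarray(groups, dtype=int),
        clusters=np.asarray(clusters),
        time_ms=counts.time_ms,
    )
    if not pseudo_population:
        return table
    return _pseudo_population(table)


def _pseudo_population(table: FeatureTable) -> FeatureTable:
    """Concatenate the k-th trial of each class across neurons (by rank)."""
    neurons = np.unique(table.groups)
    rows, labels = [], []
    for cls in (1, 0):
        per_neuron = []
        for n in neurons:
            idx = np.flatnonzero((table.groups == n) & (table.choice == cls))
            per_neuron.append(idx)
        k = min(len(ix) for ix in per_neuron)
        for r in range(k):
            rows.append(np.concatenate([table.X[ix[r]] for ix in per_neuron]))
            labels.append(cls)
    X = np.vstack(rows)
    labels = np.asarray(labels)
    return FeatureTable(
        X=X,
        choice=labels,
        rt_ms=np.full(len(labels), np.nan),
        groups=np.arange(len(labels)),
        clusters=np.zeros(len(labels), dtype=int),
        time_ms=table.time_ms,
    )


def grouped_folds(groups: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign groups to ``k`` folds balancing sample counts (greedy packing).

    Groups are shuffled, sorted by size descending (stable), and each is
    placed in the currently lightest fold.  Deterministic given the seed;
    no group ever spans two folds.
    """
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < k:
        raise ValueError(
            f"{len(uniq)} groups < {k} folds; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    order = perm[np.argsort(-counts[perm], kind="stable")]
    fold_of_group = {}
    load = np.zeros(k)
    for gi in order:
        f = int(np.argmin(load))
        fold_of_group[uniq[gi]] = f
        load[f] += counts[gi]
    return np.asarray([fold_of_group[g] for g in groups])


def _lambda_grid(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambdas: int, decades: float
) -> np.ndarray:
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / (len(y) * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-8)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambdas)


def _choice_path(Xtr, ytr, Xte, grid, alpha, max_iter, tol=1e-3):
    """Warm-started logistic elastic-net path (lambda descending).

    Returns (test decision scores per lambda, coefs per lambda).
    """
    order = np.argsort(-np.asarray(grid))
    clf = LogisticRegression(
        solver="saga", l1_ratio=alpha, warm_start=True, max_iter=max_iter, tol=tol
    )
    scores = np.empty((len(grid), len(Xte)))
    coefs = np.empty((len(grid), Xtr.shape[1]))
    for pos in order:
        clf.C = 1.0 / (len(ytr) * grid[pos])
        clf.fit(Xtr, ytr)
        scores[pos] = clf.decision_function(Xte)
        coefs[pos] = clf.coef_.ravel()
    return scores, coefs


def _rt_path(Xtr, ytr, Xte, grid, alpha, max_iter, tol=1e-4):
    order = np.argsort(-np.asarray(grid))
    reg = ElasticNet(l1_ratio=alpha, warm_start=True, max_iter=max_iter, tol=tol)
    scores = np.empty((len(grid), len(Xte)))
    coefs = np.empty((len(grid), Xtr.shape[1]))
    for pos in order:
        reg.alpha = grid[pos]
        reg.fit(Xtr, ytr)
        scores[pos] = reg.predict(Xte)
        coefs[pos] = reg.coef_.ravel()
    return scores, coefs


@dataclass
class DecodingResult:
    task: str
    score: float                   # pooled AUC (choice) or R^2 (rt)
    fold_lambdas: list[float]
    predictions: np.ndarray        # pooled out-of-fold scores, sample order
    labels: np.ndarray
    weights_ms: np.ndarray | None  # mean |time-course| of model weights
    notes: list[str] = field(default_factory=list)


def nested_cv_elastic_net(
    table: FeatureTable,
    task: str = "choice",
    alpha: float = 0.5,
    k_outer: int = 10,
    k_inner: int = 10,
    n_lambdas: int = 50,
    lambda_decades: float = 4.0,
    seed: int = 0,
    max_iter: int = 500,
    grouped: bool = True,
) -> DecodingResult:
    """Nested neuron-grouped cross-validated Elastic Net decoding.

    ``grouped=False`` splits folds at the trial level instead (every sample
    its own group) — deliberately leaky when samples from one neuron are not
    independent; provided for the leakage contrast, not for reporting.
    """
    if task not in ("choice", "rt"):
        raise ValueError("task must be 'choice' or 'rt'")
    if task == "rt":
        keep = np.isfinite(table.rt_ms)
        table = table.subset(keep)
        y = table.rt_ms
    else:
        y = table.choice
    X = table.X
    groups = table.groups if grouped else np.arange(len(y))

    folds = grouped_folds(groups, k_outer, seed)
    preds = np.full(len(y), np.nan)
    fold_lambdas, weights, notes = [], [], []
    path = _choice_path if task == "choice" else _rt_path

    for f in range(k_outer):
        te = folds == f
        tr = ~te
        if task == "choice" and len(np.unique(y[tr])) < 2:
            raise ValueError("both classes required in every outer training set")
        Xtr_raw, ytr = X[tr], y[tr]
        # Grid anchored at lambda_max of the standardized outer-training set.
        scaler = StandardScaler().fit(Xtr_raw)
        grid = _lambda_grid(
            scaler.transform(Xtr_raw), ytr.astype(float), alpha, n_lambdas,
            lambda_decades,
        )

        inner = grouped_folds(
            groups[tr], min(k_inner, len(np.unique(groups[tr]))), seed + 1
        )
        inner_scores = np.zeros(len(grid))
        for g in np.unique(inner):
            ite = inner == g
            if task == "choice" and len(np.unique(ytr[~ite])) < 2:
                notes.append(f"outer {f}: inner fold {g} skipped (one class)")
                continue
            sc = StandardScaler().fit(Xtr_raw[~ite])
            # Looser tolerance inside the selection loop: only the lambda
            # ranking matters there, not fully converged coefficients.
            p_by_lam, _ = path(
                sc.transform(Xtr_raw[~ite]), ytr[~ite],
                sc.transform(Xtr_raw[ite]), grid, alpha, max_iter,
                tol=3e-3 if task == "choice" else 1e-3,
            )
            if task == "choice":
                if len(np.unique(ytr[ite])) < 2:
                    continue
                for li in range(len(grid)):
                    inner_scores[li] += roc_auc_score(ytr[ite], p_by_lam[li])
            else:
                inner_scores -= ((ytr[ite] - p_by_lam) ** 2).mean(axis=1)
        lam_star = float(grid[int(np.argmax(inner_scores))])
        fold_lambdas.append(lam_star)
        p_by_lam, coefs = path(
            scaler.transform(Xtr_raw), ytr, scaler.transform(X[te]),
            np.asarray([lam_star]), alpha, max_iter,
        )
        preds[te] = p_by_lam[0]
        weights.append(coefs[0])

    if task == "choice":
        score = float(roc_auc_score(y, preds))
    else:
        ss_res = float(np.sum((y - preds) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        score = 1.0 - ss_res / ss_tot
    w = np.vstack(weights).mean(axis=0) if len({len(w) for w in weights}) == 1 else None
    return DecodingResult(
        task=task,
        score=score,
        fold_lambdas=fold_lambdas,
        predictions=preds,
        labels=np.asarray(y),
        weights_ms=w,
        notes=notes,
    )


def ablation_and_single_cluster(
    table: FeatureTable,
    task: str = "choice",
    pseudo_population: bool = False,
    clusters: np.ndarray | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Rerun the full nested grouped CV with clusters removed or isolated.

    ``table`` is the per-(neuron, trial) table.  With
    ``pseudo_population=True`` each subset is converted to the concatenated
    pseudo-population design before decoding, so removing a cluster removes
    its feature block rather than its samples.  ``clusters`` restricts the
    analysis to the given labels (default: all).
    """
    labels = np.unique(table.clusters) if clusters is None else np.asarray(clusters)
    if len(np.unique(table.clusters)) < 2:
        raise ValueError("need >= 2 clusters")

    def run(sub: FeatureTable) -> float:
        if pseudo_population:
            sub = _pseudo_population(sub)
        return nested_cv_elastic_net(sub, task, **cv_kwargs).score

    rows = [{"analysis": "full", "cluster": "all", "score": run(table)}]
    for lab in labels:
        for analysis, mask in (
            ("ablate", table.clusters != lab),
            ("single", table.clusters == lab),
        ):
            try:
                score = run(table.subset(mask))
            except ValueError as e:
                logger.warning("%s cluster %s not applicable: %s", analysis, lab, e)
                score = np.nan
            rows.append({"analysis": analysis, "cluster": lab, "score": score})
    return pd.DataFrame(rows)


def permutation_test(
    table: FeatureTable,
    observed_auc: float | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    **cv_kwargs,
) -> tuple[float, np.ndarray]:
    """Within-neuron label permutation null for the choice decoder.

    Shuffling within neuron preserves each neuron's class balance; neurons
    with a single class are left untouched (nothing to shuffle).  Returns
    ``(p, null_aucs)`` with ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if observed_auc is None:
        observed_auc = nested_cv_elastic_net(table, "choice", **cv_kwargs).score
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        perm = table.choice.copy()
        for g in np.unique(table.groups):
            idx = np.flatnonzero(table.groups == g)
            perm[idx] = perm[rng.permutation(idx)]
        shuffled = FeatureTable(
            table.X, perm, table.rt_ms, table.groups, table.clusters, table.time_ms
        )
        nulls[i] = nested_cv_elastic_net(
            shuffled, "choice", seed=seed + 1 + i, **{k: v for k, v in cv_kwargs.items() if k != "seed"}
        ).score
    p = (1.0 + float((nulls >= observed_auc).sum())) / (n_perm + 1.0)
    return p, nulls


class GroupedElasticNetDecoder(BaseEstimator):
    """Sklearn-style facade over the nested grouped-CV decoding procedure.

    ``fit(table)`` runs the nested cross-validation and stores the pooled
    performance; ``ablation()`` and ``permutation()`` run the follow-up
    analyses on the same table.

    Attributes
    ----------
    result_ : DecodingResult
    score_ : pooled AUC or R^2
    """

    def __init__(
        self,
        task: str = "choice",
        alpha: float = 0.5,
        k_outer: int = 10,
        k_inner: int = 10,
        n_lambdas: int = 50,
        lambda_decades: float = 4.0,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.task = task
        self.alpha = alpha
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.n_lambdas = n_lambdas
        self.lambda_decades = lambda_decades
        self.max_iter = max_iter
        self.random_state = random_state

    def _kwargs(self):
        return dict(
            alpha=self.alpha,
            k_outer=self.k_outer,
            k_inner=self.k_inner,
            n_lambdas=self.n_lambdas,
            lambda_decades=self.lambda_decades,
            max_iter=self.max_iter,
            seed=self.random_state,
        )

    def fit(self, table: FeatureTable, y=None):
        self.table_ = table
        self.result_ = nested_cv_elastic_net(table, self.task, **self._kwargs())
        self.score_ = self.result_.score
        return self

    def ablation(self) -> pd.DataFrame:
        return ablation_and_single_cluster(self.table_, self.task, **self._kwargs())

    def permutation(self, n_perm: int = 2000) -> tuple[float, np.ndarray]:
        return permutation_test(
            self.table_, self.score_, n_perm=n_perm, **self._kwargs()
        )
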