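"""Subgroup and mobility-cluster generalizability analyses.

Two questions about a depression classifier trained on a heterogeneous
cohort: (a) does the *global* model serve demographic subgroups equally
well — evaluated by slicing each outer test split by subgroup membership
and averaging subgroup AUCs over splits, then correlating subgroup size
with performance; and (b) can *dedicated* models for more homogeneous
subsets do better — evaluated by rerunning the full nested CV per
demographic subgroup, per k-means mobility cluster (computed on
depression-residualized, z-scored mobility features so the clustering
cannot encode the label), and per minimum-GPS-record threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from mobisense.modeling import (CvResult, ModelSpec, auc_score, derive_seed,
                                nested_cv_evaluate)

DEFAULT_MIN_SUBGROUP_N = 50
DEFAULT_MIN_CLUSTER_SIZE = 100
DEFAULT_K_RANGE = range(2, 16)


@dataclass
class SubgroupSpec:
    """A single- or two-attribute demographic subgroup."""

    attributes: tuple[str, ...]
    levels: tuple[str, ...]
    member_ids: frozenset

    @property
    def n(self) -> int:
        return len(self.member_ids)

    @property
    def name(self) -> str:
        return " & ".join(f"{a}={l}" for a, l in zip(self.attributes, self.levels))


@dataclass
class SubgroupEvalResult:
    subgroup: SubgroupSpec
    mean_auc: float
    n_qualifying_splits: int


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray
    retained_cluster_ids: list[int]
    inertia: float


def enumerate_subgroups(demographics: pd.DataFrame,
                        min_n: int = DEFAULT_MIN_SUBGROUP_N) -> list[SubgroupSpec]:
    """All single-attribute levels and two-attribute intersections with
    at least ``min_n`` members (boundary included), deterministically ordered."""
    demo = demographics.set_index("participant_id") if "participant_id" in demographics \
        else demographics
    attrs = sorted(demo.columns)
    out: list[SubgroupSpec] = []
    for a in attrs:
        for lv, grp in sorted(demo.groupby(a, observed=True), key=lambda t: str(t[0])):
            if len(grp) >= min_n:
                out.append(SubgroupSpec((a,), (str(lv),), frozenset(grp.index)))
    for a, b in combinations(attrs, 2):
        for (la, lb), grp in sorted(demo.groupby([a, b], observed=True),
                                    key=lambda t: (str(t[0][0]), str(t[0][1]))):
            if len(grp) >= min_n:
                out.append(SubgroupSpec((a, b), (str(la), str(lb)),
                                        frozenset(grp.index)))
    return out


def subgroup_auc_from_global(cv_result: CvResult,
                             subgroups: Sequence[SubgroupSpec]
                             ) -> list[SubgroupEvalResult]:
    """Subgroup performance of the globally trained model.

    Per subgroup and outer split, AUC over the subgroup's members in that
    split's test set (only when both classes are present there); the
    subgroup metric is the mean over qualifying splits, keeping the unit of
    analysis identical to the global per-split metric.  Subgroups with zero
    qualifying splits get mean_auc = NaN.
    """
    out = []
    for sg in subgroups:
        aucs = []
        for ids, lab, sco in zip(cv_result.test_ids, cv_result.test_labels,
                                 cv_result.test_scores):
            m = np.fromiter((i in sg.member_ids for i in ids), dtype=bool,
                            count=len(ids))
            if m.sum() >= 2 and len(np.unique(lab[m])) == 2:
                aucs.append(auc_score(lab[m], sco[m]))
        out.append(SubgroupEvalResult(
            subgroup=sg,
            mean_auc=float(np.mean(aucs)) if aucs else float("nan"),
            n_qualifying_splits=len(aucs)))
    return out


def correlate_size_performance(results: Sequence[SubgroupEvalResult]
                               ) -> tuple[float, int, float]:
    """Pearson correlation of subgroup size with subgroup mean AUC.

    Returns (r, df = n − 2, two-sided p); (nan, df, nan) when either vector
    has zero variance or fewer than 3 subgroups carry an AUC.
    """
    pairs = [(r.subgroup.n, r.mean_auc) for r in results
             if np.isfinite(r.mean_auc)]
    if len(pairs) < 3:
        return float("nan"), max(0, len(pairs) - 2), float("nan")
    n, a = np.array(pairs).T
    df = len(pairs) - 2
    if np.std(n) == 0 or np.std(a) == 0:
        return float("nan"), df, float("nan")
    r, p = stats.pearsonr(n, a)
    return float(r), df, float(p)


def train_subgroup_models(X: np.ndarray, y: np.ndarray, ids: Sequence,
                          subgroups: Sequence[SubgroupSpec], spec: ModelSpec,
                          n_outer: int = 100, seed: int = 0,
                          min_n: int = DEFAULT_MIN_SUBGROUP_N
                          ) -> tuple[dict[str, CvResult], dict[str, str]]:
    """Run the full nested-CV pipeline independently per subgroup.

    Subgroups failing the preconditions (too small, single class) are
    skipped with a logged reason.  Returns ({name: CvResult}, {name: skip
    reason}).
    """
    ids = np.asarray(ids)
    results: dict[str, CvResult] = {}
    skipped: dict[str, str] = {}
    for gi, sg in enumerate(subgroups):
        m = np.fromiter((i in sg.member_ids for i in ids), dtype=bool,
                        count=len(ids))
        ysub = y[m]
        if m.sum() < max(min_n, 20):
            skipped[sg.name] = f"too few members (n={int(m.sum())})"
            continue
        if len(np.unique(ysub)) < 2 or np.bincount(ysub.astype(int)).min() < 5:
            skipped[sg.name] = "single or near-single class"
            continue
        try:
            results[sg.name] = nested_cv_evaluate(
                X[m], ysub, spec, n_outer=n_outer, seed=derive_seed(seed, gi),
                ids=ids[m])
        except ValueError as err:
            skipped[sg.name] = f"nested CV failed: {err}"
    return results, skipped


def residualize_features(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial the binary label out of every column.

    OLS of each column on (intercept, y) reduces, for a binary regressor,
    to subtracting the per-class mean; residual columns therefore have zero
    mean and zero covariance with the label.  Constant columns residualize
    to all-zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("residualization requires both classes")
    R = X.copy()
    for cls in (0, 1):
        m = y == cls
        R[m] -= X[m].mean(axis=0)
    return R


def kmeans_mobility_clusters(residuals: np.ndarray,
                             k_range: Sequence[int] = DEFAULT_K_RANGE,
                             min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
                             seed: int = 0, n_restarts: int = 10
                             ) -> list[ClusteringResult]:
    """k-means over z-scored residual mobility features for each k.

    Clusters with ``min_cluster_size`` or fewer members are excluded from
    downstream modelling (their membership is retained for reporting).
    """
    R = np.asarray(residuals, dtype=float)
    R = np.where(np.isnan(R), 0.0, R)
    sd = R.std(axis=0, ddof=0)
    Z = (R - R.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    out = []
    for k in k_range:
        if k > Z.shape[0]:
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=derive_seed(seed, k)).fit(Z)
        sizes = np.bincount(km.labels_, minlength=k)
        retained = [int(c) for c in range(k) if sizes[c] > min_cluster_size]
        out.append(ClusteringResult(k=k, labels=km.labels_.copy(),
                                    retained_cluster_ids=retained,
                                    inertia=float(km.inertia_)))
    return out


def evaluate_clusters(X: np.ndarray, y: np.ndarray, ids: Sequence,
                      clustering: ClusteringResult, spec: ModelSpec,
                      n_outer: int = 100, seed: int = 0
                      ) -> tuple[dict[int, CvResult], dict[int, str]]:
    """Nested CV per retained mobility cluster."""
    ids = np.asarray(ids)
    results: dict[int, CvResult] = {}
    skipped: dict[int, str] = {}
    for c in clustering.retained_cluster_ids:
        m = clustering.labels == c
        ysub = y[m]
        if len(np.unique(ysub)) < 2 or np.bincount(ysub.astype(int)).min() < 5:
            skipped[c] = "single or near-single class"
            continue
        try:
            results[c] = nested_cv_evaluate(X[m], ysub, spec, n_outer=n_outer,
                                            seed=derive_seed(seed, clustering.k, c),
                                            ids=ids[m])
        except ValueError as err:
            skipped[c] = f"nested CV failed: {err}"
    return results, skipped


def cluster_auc_table(per_k: Mapping[int, Mapping[int, CvResult]]) -> pd.DataFrame:
    """Tidy per-k summary of retained-cluster AUC distributions."""
    rows = []
    for k, clusters in sorted(per_k.items()):
        for c, res in sorted(clusters.items()):
            rows.append({"k": k, "cluster": c, "n_test": len(res.test_ids[0]),
                         "mean_auc": res.mean_auc, "ci95": res.ci95})
    return pd.DataFrame(rows, columns=["k", "cluster", "n_test", "mean_auc", "ci95"])


def gps_threshold_sweep(X: np.ndarray, y: np.ndarray, ids: Sequence,
                        gps_counts: Mapping[str, int],
                        spec: ModelSpec, thresholds: Sequence[int] | None = None,
                        n_outer: int = 25, seed: int = 0) -> pd.DataFrame:
    """Refilter by total GPS records >= threshold and rerun nested CV.

    Returns a tidy frame (threshold, n_retained, mean_auc, ci95, feasible);
    thresholds leaving fewer than 20 participants or a single class are
    marked infeasible.
    """
    if thresholds is None:
        thresholds = list(range(1000, 10001, 1000))
    ids = np.asarray(ids)
    counts = np.array([int(gps_counts.get(i, 0)) for i in ids])
    rows = []
    for ti, thr in enumerate(sorted(thresholds)):
        m = counts >= thr
        row = {"threshold": int(thr), "n_retained": int(m.sum()),
               "mean_auc": float("nan"), "ci95": float("nan"), "feasible": False}
        ysub = y[m]
        if m.sum() >= 20 and len(np.unique(ysub)) == 2 \
                and np.bincount(ysub.astype(int)).min() >= 4:
            res = nested_cv_evaluate(X[m], ysub, spec, n_outer=n_outer,
                                     seed=derive_seed(seed, ti), ids=ids[m])
            row.update(mean_auc=res.mean_auc, ci95=res.ci95, feasible=True)
        rows.append(row)
    return pd.DataFrame(rows)
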