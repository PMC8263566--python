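"""Depression classification under nested Monte-Carlo cross-validation.

Three classifier families are supported — penalized logistic regression,
random forest, and XGBoost — evaluated with an outer Monte-Carlo loop of
stratified 80/20 splits (default 100) and an inner 3-fold grid search that
picks the hyperparameter configuration with the highest mean AUC-ROC.
Missing values are mean-imputed and (for the logistic model only) columns
are z-standardized; both statistics, as well as the optional top-k filter
feature selection, are fit on the training fold of each outer split only,
so no information leaks from a split's test participants into its model.

AUC is reported per outer split; the summary is the arithmetic mean with a
normal-theory 95% half-width 1.96 * sd / sqrt(n_outer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

MODEL_KINDS = ("penalized_logistic", "random_forest", "xgboost")
FEATURE_BLOCKS = ("mobility", "steps", "demographics", "all")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "penalized_logistic": {
        "penalty": ["l1", "l2"],
        "C": list(np.logspace(-3, 3, 7)),
    },
    "random_forest": {
        "n_estimators": [100, 500],
        "max_depth": [3, 10, None],
        "max_features": ["sqrt", 0.3],
    },
    "xgboost": {
        "learning_rate": [0.03, 0.1, 0.3],
        "max_depth": [2, 4, 6],
        "n_estimators": [50, 200],
        "subsample": [0.8, 1.0],
    },
}

#: compact grids for quick experiments and sweeps.
SMALL_GRIDS: dict[str, dict[str, list]] = {
    "penalized_logistic": {"penalty": ["l2"], "C": [0.01, 0.1, 1.0]},
    "random_forest": {"n_estimators": [200], "max_depth": [5, None],
                      "max_features": ["sqrt"]},
    "xgboost": {"learning_rate": [0.1], "max_depth": [2, 4],
                "n_estimators": [100], "subsample": [1.0]},
}


@dataclass
class ModelSpec:
    """Classifier family + hyperparameter grid + feature block."""

    kind: str = "penalized_logistic"
    grid: Mapping[str, Sequence] | None = None
    feature_block: str = "all"
    feature_selection_k: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.feature_block not in FEATURE_BLOCKS:
            raise ValueError(f"unknown feature block {self.feature_block!r}")
        if self.grid is None:
            self.grid = DEFAULT_GRIDS[self.kind]
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    def configurations(self) -> list[dict]:
        names = list(self.grid)
        return [dict(zip(names, combo))
                for combo in product(*(self.grid[n] for n in names))]


@dataclass
class CvResult:
    """Per-outer-split AUCs plus retained test predictions."""

    aucs: list[float]
    test_ids: list[np.ndarray]
    test_labels: list[np.ndarray]
    test_scores: list[np.ndarray]
    chosen_params: list[dict]
    coefficients: np.ndarray | None = None   # splits x features (logistic only)
    feature_names: list[str] | None = None

    @property
    def n_outer(self) -> int:
        return len(self.aucs)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def ci95(self) -> float:
        if len(self.aucs) < 2:
            return float("nan")
        return float(1.96 * np.std(self.aucs, ddof=1) / np.sqrt(len(self.aucs)))


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and indices."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


class FoldPreprocessor:
    """Training-fold-only imputation (+ z-scaling for the logistic model)."""

    def __init__(self, scale: bool):
        self.scale = scale
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FoldPreprocessor":
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            means = np.nanmean(X, axis=0)
        means = np.where(np.isfinite(means), means, 0.0)  # all-missing -> 0
        self.means_ = means
        if self.scale:
            Xi = np.where(np.isnan(X), means, X)
            sds = Xi.std(axis=0, ddof=0)
            self.sds_ = np.where(sds > 0, sds, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xi = np.where(np.isnan(X), self.means_, X)
        if self.scale:
            Xi = (Xi - self.means_) / self.sds_
        return Xi


def prepare_matrix(X_train: np.ndarray, X_test: np.ndarray, model_kind: str
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Impute (and, for logistic, standardize) using training statistics only."""
    prep = FoldPreprocessor(scale=model_kind == "penalized_logistic").fit(X_train)
    return prep.transform(X_train), prep.transform(X_test)


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC-ROC: P(random positive outranks random negative), ties = 1/2."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def make_estimator(kind: str, params: Mapping, seed: int):
    if kind == "penalized_logistic":
        params = dict(params)
        # grids name the penalty l1/l2; recent sklearn spells this l1_ratio
        penalty = params.pop("penalty", "l2")
        params.setdefault("l1_ratio", 1.0 if str(penalty).lower() == "l1" else 0.0)
        return LogisticRegression(solver="liblinear", max_iter=2000,
                                  random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", **params)
    raise ValueError(f"unknown model kind {kind!r}")


def select_features(X_train: np.ndarray, y_train: np.ndarray, k: int = 50
                    ) -> np.ndarray:
    """Top-k column indices by |point-biserial correlation| with the label.

    Fit on the training fold only; with k >= n_columns this is the identity
    selection.  Constant columns score 0.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    p = X.shape[1]
    if k >= p:
        return np.arange(p)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = X.std(axis=0, ddof=0)
    sy = y.std(ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (sx * sy)
    r = np.where(np.isfinite(r), r, 0.0)
    order = np.argsort(-np.abs(r), kind="stable")
    return np.sort(order[:k])


def inner_tune(X_train: np.ndarray, y_train: np.ndarray, spec: ModelSpec,
               k: int = 3, seed: int = 0) -> dict:
    """Exhaustive 3-fold grid search on the training fold; argmax mean AUC.

    Ties break toward the earlier configuration in grid order.
    """
    configs = spec.configurations()
    if len(configs) == 1:
        return configs[0]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    folds = list(skf.split(X_train, y_train))
    best, best_auc = configs[0], -np.inf
    for ci, cfg in enumerate(configs):
        aucs = []
        for fi, (tr, va) in enumerate(folds):
            if len(np.unique(y_train[va])) < 2:
                continue
            Xtr, Xva = prepare_matrix(X_train[tr], X_train[va], spec.kind)
            est = make_estimator(spec.kind, cfg, derive_seed(seed, ci, fi))
            est.fit(Xtr, y_train[tr])
            aucs.append(auc_score(y_train[va], est.predict_proba(Xva)[:, 1]))
        mean = np.mean(aucs) if aucs else -np.inf
        if mean > best_auc:
            best, best_auc = cfg, mean
    return best


def monte_carlo_splits(y: np.ndarray, n_outer: int, test_frac: float, seed: int
                       ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """The outer stratified 80/20 partitions, seed-derived per split index."""
    y = np.asarray(y).astype(int)
    for s in range(n_outer):
        sss = StratifiedShuffleSplit(n_splits=1, test_size=test_frac,
                                     random_state=derive_seed(seed, s))
        tr, te = next(sss.split(np.zeros((y.size, 1)), y))
        yield tr, te


def nested_cv_evaluate(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                       n_outer: int = 100, test_frac: float = 0.2,
                       seed: int = 0, ids: Sequence | None = None,
                       feature_names: Sequence[str] | None = None,
                       splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None
                       ) -> CvResult:
    """Nested Monte-Carlo cross-validation.

    Outer loop: ``n_outer`` stratified 80/20 splits; inner loop: 3-fold grid
    search on the 80%.  Per split the tuned model is refit on the full
    training fold and scored (class-1 probability) on the 20% test fold.
    ``splits`` substitutes precomputed outer partitions (n_outer is then
    ignored).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("nested CV requires both classes present")
    if counts.min() < 2 or y.size < 20:
        raise ValueError(
            f"too few participants to stratify (n={y.size}, "
            f"minority={int(counts.min())}; need n >= 20 and >= 2 per class)")
    ids = np.asarray(ids if ids is not None else np.arange(y.size))

    aucs, t_ids, t_lab, t_sco, chosen = [], [], [], [], []
    coefs = [] if spec.kind == "penalized_logistic" else None
    p = X.shape[1]
    outer = splits if splits is not None \
        else monte_carlo_splits(y, n_outer, test_frac, seed)
    for s, (tr, te) in enumerate(outer):
        cols = np.arange(p)
        if spec.feature_selection_k is not None:
            prep = FoldPreprocessor(scale=False).fit(X[tr])
            cols = select_features(prep.transform(X[tr]), y[tr],
                                   spec.feature_selection_k)
        Xs = X[:, cols]
        split_seed = derive_seed(seed, s, 1)
        best = inner_tune(Xs[tr], y[tr], spec, seed=split_seed)
        Xtr, Xte = prepare_matrix(Xs[tr], Xs[te], spec.kind)
        est = make_estimator(spec.kind, best, derive_seed(seed, s, 2))
        est.fit(Xtr, y[tr])
        scores = est.predict_proba(Xte)[:, 1]
        aucs.append(auc_score(y[te], scores))
        t_ids.append(ids[te])
        t_lab.append(y[te])
        t_sco.append(scores)
        chosen.append(best)
        if coefs is not None:
            full = np.full(p, np.nan)
            full[cols] = est.coef_.ravel()
            coefs.append(full)
    return CvResult(aucs=aucs, test_ids=t_ids, test_labels=t_lab,
                    test_scores=t_sco, chosen_params=chosen,
                    coefficients=np.array(coefs) if coefs is not None else None,
                    feature_names=list(feature_names) if feature_names is not None else None)


def compare_auc_distributions(aucs_a: Sequence[float], aucs_b: Sequence[float]
                              ) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U comparison of two AUC distributions.

    U is reported for the first sample; exact p for small tie-free samples,
    tie-corrected normal approximation otherwise (scipy's policy).
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both AUC lists must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return MannWhitneyResult(u_statistic=float(res.statistic),
                             p_value=float(res.pvalue), n1=a.size, n2=b.size)


def coefficient_report(result: CvResult) -> pd.DataFrame:
    """Mean standardized logistic coefficient per feature across outer splits.

    Ranked by |mean|; the sign column gives the direction of association
    with the depressed class.  Raises for tree models, whose coefficients
    are undefined (impurity importances are out of scope here).
    """
    if result.coefficients is None:
        raise ValueError("coefficient report requires penalized_logistic results")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # never-selected columns
        mean = np.nanmean(result.coefficients, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    names = result.feature_names or [f"x{i}" for i in range(mean.size)]
    df = pd.DataFrame({"feature": names, "mean_coefficient": mean})
    df["sign"] = np.sign(df["mean_coefficient"]).astype(int)
    return df.reindex(df["mean_coefficient"].abs().sort_values(ascending=False).index
                      ).reset_index(drop=True)


def cv_summary(result: CvResult) -> dict:
    return {"mean_auc": result.mean_auc, "ci95": result.ci95,
            "n_outer": result.n_outer}
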