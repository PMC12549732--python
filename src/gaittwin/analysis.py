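"""Risk stratification: preprocessing, clustering, classification, attribution.

Stages mirror a standard small-cohort clinical ML workflow: mean/median
imputation, min-max scaling, class weighting and SMOTE for the 8-vs-38 class
imbalance, t-SNE for visual QC, repeated k-means (k=2, 30 runs) with
centroid-difference feature importance and per-cluster KDE, stratified 75/25
train/test evaluation with randomized hyper-parameter search under 5-fold CV
scored by balanced accuracy, and permutation-based feature attribution.

All fitting (imputation statistics, scaling bounds, SMOTE) happens on
training data only; the test partition is never touched before evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, rankdata
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.model_selection import (RandomizedSearchCV, StratifiedKFold,
                                     train_test_split)
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import AmbiguousSolution, NoSolution, ValidationError

POSITIVE = "high"


def _as_frame(X) -> pd.DataFrame:
    return X.copy() if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Preprocessing

def impute(table: pd.DataFrame, strategy: str = "median"
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing cells by the column mean or median of observed values.

    Returns the imputed table and the boolean imputation mask.
    """
    if strategy not in ("mean", "median"):
        raise ValidationError(f"unknown imputation strategy {strategy!r}")
    out = table.copy()
    mask = table.isna()
    for col in table.columns:
        if mask[col].all():
            raise ValidationError(f"column {col!r} is entirely missing")
        if mask[col].any():
            stat = table[col].mean() if strategy == "mean" else table[col].median()
            out[col] = out[col].fillna(stat)
    return out, mask


@dataclass
class MinMaxParams:
    mins: pd.Series
    maxs: pd.Series


def minmax_scale(table: pd.DataFrame) -> tuple[pd.DataFrame, MinMaxParams]:
    """(x - min) / (max - min) per feature; constant features map to 0."""
    if table.isna().any().any():
        raise ValidationError("impute before scaling")
    mins, maxs = table.min(), table.max()
    span = maxs - mins
    constant = span == 0
    if constant.any():
        warnings.warn(f"constant features scaled to 0: {list(table.columns[constant])}")
    span = span.replace(0, 1.0)
    return (table - mins) / span, MinMaxParams(mins=mins, maxs=maxs)


def minmax_apply(table: pd.DataFrame, params: MinMaxParams) -> pd.DataFrame:
    span = (params.maxs - params.mins).replace(0, 1.0)
    return (table - params.mins) / span


def minmax_invert(scaled: pd.DataFrame, params: MinMaxParams) -> pd.DataFrame:
    span = (params.maxs - params.mins).replace(0, 1.0)
    return scaled * span + params.mins


def class_weights(labels) -> dict:
    """w_c = n_total / (n_classes * n_c), inverse-frequency weighting."""
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValidationError("class weighting needs both classes present")
    n = counts.sum()
    return {c: float(n / (len(counts) * k)) for c, k in counts.items()}


def smote_oversample(X, y, k_neighbors: int = 5, seed: int = 0
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic minority oversampling by interpolation between neighbours.

    Each synthetic sample is x_i + u (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn one of the k nearest minority neighbours of x_i. The minority class
    is brought up to the majority count. Deterministic given ``seed``.
    """
    X = _as_frame(X)
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    if len(counts) != 2:
        raise ValidationError("SMOTE expects exactly two classes")
    minority = counts.idxmin()
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= k_neighbors:
        raise ValidationError(
            f"minority count {n_min} <= k_neighbors {k_neighbors}; "
            "reduce k_neighbors below the minority size")
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X, y
    rng = np.random.default_rng(seed)
    Xm = X[y == minority].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)     # column 0 is the point itself
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    u = rng.uniform(size=n_new)[:, None]
    synth = Xm[base] + u * (Xm[idx[base, pick]] - Xm[base])
    X_out = pd.concat([X, pd.DataFrame(synth, columns=X.columns)], ignore_index=True)
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Embedding and clustering

def embed_2d(X, seed: int = 0, perplexity: float = 10.0
             ) -> tuple[np.ndarray, float]:
    """t-SNE projection for visual QC, with a neighbourhood-preservation score
    (mean fraction of each point's 5 nearest neighbours preserved)."""
    X = _as_frame(X).to_numpy(dtype=float)
    n = len(X)
    if n < 3 * perplexity:
        raise ValidationError(f"n={n} too small for perplexity {perplexity}")
    coords = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                  init="pca").fit_transform(X)
    k = min(5, n - 1)
    nn_hi = NearestNeighbors(n_neighbors=k + 1).fit(X).kneighbors(X)[1][:, 1:]
    nn_lo = NearestNeighbors(n_neighbors=k + 1).fit(coords).kneighbors(coords)[1][:, 1:]
    score = float(np.mean([len(set(a) & set(b)) / k for a, b in zip(nn_hi, nn_lo)]))
    return coords, score


@dataclass
class ClusterResult:
    assignments: np.ndarray            # (runs, n) matched labels
    consensus: np.ndarray              # (n,) majority label
    centroids: np.ndarray              # (runs, 2, n_features)
    importance_mean: pd.Series         # |c0 - c1| per feature, mean over runs
    importance_sd: pd.Series
    kde: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)


def kmeans_repeated(X, k: int = 2, runs: int = 30, seed: int = 0,
                    kde_top: int = 5) -> ClusterResult:
    """Repeated k-means (k=2) with matched labels across runs.

    Cluster labels of each run are aligned to the first run by centroid
    proximity; the consensus assignment is the per-sample majority. Feature
    importance is the absolute centroid difference per (scaled) feature,
    reported as mean +- SD over runs, with Gaussian KDE (Silverman bandwidth)
    of the top features per cluster.
    """
    if k != 2:
        raise ValidationError("this pipeline clusters with k=2")
    Xf = _as_frame(X)
    arr = Xf.to_numpy(dtype=float)
    if len(arr) < k:
        raise ValidationError("fewer samples than clusters")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=runs)
    assignments, centroids = [], []
    for s in run_seeds:
        km = KMeans(n_clusters=2, n_init=10, random_state=int(s)).fit(arr)
        lab, cen = km.labels_, km.cluster_centers_
        if centroids:
            ref = centroids[0]
            # match by total centroid distance under the two label mappings
            direct = np.linalg.norm(cen - ref)
            swapped = np.linalg.norm(cen[::-1] - ref)
            if swapped < direct:
                lab, cen = 1 - lab, cen[::-1]
        assignments.append(lab)
        centroids.append(cen)
    assignments = np.asarray(assignments)
    centroids = np.asarray(centroids)
    consensus = (assignments.mean(axis=0) >= 0.5).astype(int)
    diffs = np.abs(centroids[:, 0, :] - centroids[:, 1, :])
    imp_mean = pd.Series(diffs.mean(axis=0), index=Xf.columns).sort_values(ascending=False)
    imp_sd = pd.Series(diffs.std(axis=0), index=Xf.columns)[imp_mean.index]

    kde: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for feat in imp_mean.index[:kde_top]:
        kde[feat] = {}
        grid = np.linspace(float(Xf[feat].min()), float(Xf[feat].max()), 100)
        for c in (0, 1):
            vals = Xf[feat].to_numpy()[consensus == c]
            if len(vals) > 1 and np.std(vals) > 0:
                kde[feat][c] = (grid, gaussian_kde(vals)(grid))
    return ClusterResult(assignments=assignments, consensus=consensus,
                         centroids=centroids, importance_mean=imp_mean,
                         importance_sd=imp_sd, kde=kde)


# ---------------------------------------------------------------------------
# Classification metrics

def _round2(x: float) -> float:
    """Round half-up at 2 decimal places."""
    return float(np.floor(x * 100 + 0.5) / 100)


def rank_auc(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Rank-statistic AUC (Mann-Whitney; ties get half credit)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class ClassifierReport:
    model: str
    TP: int
    FP: int
    FN: int
    TN: int
    Acc: float = field(init=False)
    BA: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    F1: float = field(init=False)
    MCC: float = field(init=False)
    AUC: Optional[float] = None
    search_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tp, fp, fn, tn = self.TP, self.FP, self.FN, self.TN
        n = tp + fp + fn + tn
        if n < 1 or min(tp, fp, fn, tn) < 0:
            raise ValidationError("invalid confusion matrix")
        self.Acc = (tp + tn) / n
        self.precision = tp / (tp + fp) if tp + fp else 0.0
        self.recall = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        self.BA = (self.recall + spec) / 2
        pr = self.precision + self.recall
        self.F1 = 2 * self.precision * self.recall / pr if pr else 0.0
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        self.MCC = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom else 0.0

    def rounded(self) -> dict[str, float]:
        out = {m: _round2(getattr(self, m))
               for m in ("Acc", "BA", "precision", "recall", "F1", "MCC")}
        if self.AUC is not None:
            out["AUC"] = _round2(self.AUC)
        return out


def evaluate_classifier(TP: int, FP: int, FN: int, TN: int,
                        scores: Optional[np.ndarray] = None,
                        y_true: Optional[np.ndarray] = None,
                        model: str = "") -> ClassifierReport:
    """Build the full metric report from a confusion matrix (+ score vector).

    AUC is computed from the scores by rank statistic when provided; the
    remaining metrics are closed forms of the counts, with the conventions
    precision = 0 when TP+FP = 0, F1 = 0 when P+R = 0, MCC = 0 when any
    marginal is 0.
    """
    rep = ClassifierReport(model=model, TP=TP, FP=FP, FN=FN, TN=TN)
    if scores is not None:
        if y_true is None or len(scores) != len(y_true):
            raise ValidationError("scores and y_true must have equal length")
        rep.AUC = rank_auc(scores, y_true)
    return rep


def confusion_from_metrics(n_test: int, n_pos: int, acc: float,
                           precision: float, recall: float
                           ) -> tuple[int, int, int, int]:
    """Unique integer confusion matrix reproducing printed metrics at 2 d.p.

    Exhaustive search over matrices with TP + FN = n_pos and total = n_test;
    raises ``NoSolution`` / ``AmbiguousSolution`` otherwise.
    """
    for v in (acc, precision, recall):
        if not 0 <= v <= 1:
            raise ValidationError("metrics must lie in [0, 1]")
    sols = []
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        for fp in range(n_test - n_pos + 1):
            tn = n_test - n_pos - fp
            rep = ClassifierReport(model="", TP=tp, FP=fp, FN=fn, TN=tn)
            if (_round2(rep.Acc) == _round2(acc)
                    and _round2(rep.precision) == _round2(precision)
                    and _round2(rep.recall) == _round2(recall)):
                sols.append((tp, fp, fn, tn))
    if not sols:
        raise NoSolution(f"no confusion matrix matches {acc}/{precision}/{recall}")
    if len(sols) > 1:
        raise AmbiguousSolution(f"{len(sols)} matrices match: {sols}")
    return sols[0]


# ---------------------------------------------------------------------------
# Training

def _make_model(name: str, weights: Optional[dict], seed: int):
    """Learner + hyper-parameter distributions for randomized search."""
    cw = {0: weights["low"], 1: weights[POSITIVE]} if weights else None
    if name == "logreg":
        return (LogisticRegression(max_iter=5000, class_weight=cw),
                {"C": np.logspace(-2, 2, 20)})
    if name == "svm":
        return (SVC(kernel="linear", class_weight=cw, probability=False),
                {"C": np.logspace(-2, 2, 20)})
    if name == "dtree":
        return (DecisionTreeClassifier(class_weight=cw, random_state=seed),
                {"max_depth": [2, 3, 4, 5, None], "min_samples_leaf": [1, 2, 3, 5]})
    if name == "rf":
        return (RandomForestClassifier(class_weight=cw, random_state=seed,
                                       n_estimators=100),
                {"max_depth": [2, 3, 5, None], "min_samples_leaf": [1, 2, 3],
                 "max_features": ["sqrt", 0.5]})
    if name == "xgboost":
        spw = (weights[POSITIVE] / weights["low"]) if weights else 1.0
        return (XGBClassifier(eval_metric="logloss", random_state=seed,
                              scale_pos_weight=spw, n_estimators=100),
                {"max_depth": [2, 3, 4], "learning_rate": [0.05, 0.1, 0.3],
                 "subsample": [0.7, 1.0], "reg_lambda": [0.5, 1.0, 2.0]})
    raise ValidationError(f"unknown model {name!r}")

MODEL_NAMES = ("logreg", "svm", "dtree", "rf", "xgboost")


@dataclass
class TrainResult:
    report: ClassifierReport
    estimator: object
    feature_names: list[str]
    X_test: pd.DataFrame
    y_test: np.ndarray
    train_index: np.ndarray
    test_index: np.ndarray


def _scores_of(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def train_and_evaluate(features: pd.DataFrame, labels, model_spec: str = "xgboost",
                       split: float = 0.75, cv_folds: int = 5, seed: int = 0,
                       use_smote: bool = False, n_iter: int = 15,
                       impute_strategy: str = "median") -> TrainResult:
    """Stratified split, randomized search under CV, held-out evaluation.

    Imputation statistics and min-max bounds are fit on the training
    partition only and applied to the test partition; SMOTE, when enabled,
    augments only the training rows. Search is scored by balanced accuracy
    under stratified ``cv_folds``-fold CV (folds are reduced with a warning
    if the minority class is smaller than the fold count).
    """
    X = _as_frame(features)
    y_raw = pd.Series(labels).reset_index(drop=True)
    if y_raw.value_counts().min() < 2:
        raise ValidationError("need >= 2 examples per class")
    y = (y_raw == POSITIVE).astype(int).to_numpy()

    idx = np.arange(len(X))
    tr_idx, te_idx = train_test_split(idx, train_size=split, stratify=y,
                                      random_state=seed)
    X_tr_raw, X_te_raw = X.iloc[tr_idx], X.iloc[te_idx]
    y_tr, y_te = y[tr_idx], y[te_idx]

    X_tr, _ = impute(X_tr_raw.reset_index(drop=True), impute_strategy)
    # test-set missing values filled from TRAINING statistics
    stats = X_tr_raw.mean() if impute_strategy == "mean" else X_tr_raw.median()
    X_te = X_te_raw.reset_index(drop=True).fillna(stats)
    X_tr, mm = minmax_scale(X_tr)
    X_te = minmax_apply(X_te, mm)

    weights = class_weights(y_raw.iloc[tr_idx])
    if use_smote:
        k = min(5, int((y_tr == 1).sum()) - 1)
        X_tr, y_tr = smote_oversample(X_tr, y_tr, k_neighbors=max(1, k), seed=seed)
        weights = None

    n_min = int(pd.Series(y_tr).value_counts().min())
    folds = cv_folds
    if n_min < cv_folds:
        warnings.warn(f"minority class has {n_min} members; reducing CV folds")
        folds = max(2, n_min)
    est, grid = _make_model(model_spec, weights, seed)
    search = RandomizedSearchCV(
        est, grid, n_iter=n_iter, scoring="balanced_accuracy",
        cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X_tr, y_tr)
    best = search.best_estimator_

    pred = best.predict(X_te)
    tp = int(np.sum((pred == 1) & (y_te == 1)))
    fp = int(np.sum((pred == 1) & (y_te == 0)))
    fn = int(np.sum((pred == 0) & (y_te == 1)))
    tn = int(np.sum((pred == 0) & (y_te == 0)))
    rep = evaluate_classifier(tp, fp, fn, tn, scores=_scores_of(best, X_te),
                              y_true=y_te, model=model_spec)
    rep.search_meta = {"best_params": {k: (v.item() if hasattr(v, "item") else v)
                                       for k, v in search.best_params_.items()},
                       "cv_score": float(search.best_score_), "cv_folds": folds,
                       "smote": use_smote, "seed": seed}
    return TrainResult(report=rep, estimator=best, feature_names=list(X.columns),
                       X_test=X_te, y_test=y_te, train_index=tr_idx, test_index=te_idx)


# ---------------------------------------------------------------------------
# Attribution

def feature_attribution(model, X_test: pd.DataFrame, y_test, repeats: int = 30,
                        seed: int = 0, exact: bool = False) -> pd.DataFrame:
    """Permutation importance: mean balanced-accuracy drop per shuffled feature.

    The sign column carries the direction of association (correlation of the
    feature with the predicted score). With ``exact=True`` and an XGBoost
    learner, exact additive attributions (mean |pred_contribs|) are used
    instead of permutation.
    """
    X = _as_frame(X_test).reset_index(drop=True)
    y = np.asarray(y_test)
    rng = np.random.default_rng(seed)
    scores = _scores_of(model, X)

    if exact and isinstance(model, XGBClassifier):
        contribs = model.get_booster().predict(
            __import__("xgboost").DMatrix(X), pred_contribs=True)
        imp = np.abs(contribs[:, :-1]).mean(axis=0)
        sds = np.zeros_like(imp)
    else:
        def ba(y_true, y_pred):
            rep = ClassifierReport(model="", TP=int(np.sum((y_pred == 1) & (y_true == 1))),
                                   FP=int(np.sum((y_pred == 1) & (y_true == 0))),
                                   FN=int(np.sum((y_pred == 0) & (y_true == 1))),
                                   TN=int(np.sum((y_pred == 0) & (y_true == 0))))
            return rep.BA
        base = ba(y, model.predict(X))
        imp = np.zeros(X.shape[1])
        sds = np.zeros(X.shape[1])
        for j, col in enumerate(X.columns):
            drops = np.empty(repeats)
            for r in range(repeats):
                Xp = X.copy()
                Xp[col] = rng.permutation(Xp[col].to_numpy())
                drops[r] = base - ba(y, model.predict(Xp))
            imp[j], sds[j] = drops.mean(), drops.std()

    signs = np.zeros(X.shape[1])
    for j, col in enumerate(X.columns):
        v = X[col].to_numpy()
        if np.std(v) > 0 and np.std(scores) > 0:
            signs[j] = np.sign(np.corrcoef(v, scores)[0, 1])
    out = pd.DataFrame({"feature": list(X.columns), "importance": imp,
                        "importance_sd": sds, "direction": signs})
    return out.sort_values("importance", ascending=False, kind="mergesort"
                           ).reset_index(drop=True)
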