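"""Feature selection and imbalance-aware classification.

* :func:`rsfs_select` — random-subset feature selection: random feature
  subsets are scored with a kNN classifier by unweighted average recall
  (UAR); each participating feature accumulates the subset's UAR excess over
  the running mean, and a feature is kept when its cumulative relevance
  exceeds what a random walk of the same length would produce.
* :func:`undersample_near_boundary` — keeps every positive and only the
  negatives closest (in standardized feature space) to a positive, i.e. the
  hard negatives near the decision boundary.
* :func:`train_wsvm` — RBF-kernel SVM with a per-class misclassification
  weight compensating the residual class imbalance.
* :func:`two_layer_cv` — outer K folds estimate performance while inner L
  folds grid-search (sample ratio, cost, gamma) by mean Gmean, the
  imbalance-robust model-selection score sqrt(sensitivity x specificity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.metrics import roc_auc_score
from scipy.spatial.distance import cdist


def gmean(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity (TP/(TP+FN)) and specificity (TN/(TN+FP))."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    return float(np.sqrt(sensitivity * specificity))


def _rates(y_true, y_pred) -> tuple[float, float]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = ~pos
    sens = float(np.mean(y_pred[pos] == 1)) if pos.any() else 0.0
    spec = float(np.mean(y_pred[neg] == 0)) if neg.any() else 0.0
    return sens, spec


# --------------------------------------------------------------- RSFS


def rsfs_select(X: np.ndarray, y: np.ndarray, iterations: int = 600, seed: int = 0,
                *, feature_names=None, k: int = 3, subset_prob: float = 0.5,
                c: float = 1.96, dev_fraction: float = 0.3) -> list:
    """Random-subset feature selection.

    Each iteration draws a feature subset (every feature independently with
    probability *subset_prob*), trains a kNN (k neighbors) on a freshly drawn
    stratified train split and scores the held-out split by unweighted
    average recall (UAR).  Re-splitting every iteration keeps chance
    feature/label correlations from persisting, which the random-walk null
    below assumes.  Feature relevance accumulates the per-iteration deviation
    from the running mean UAR; after all iterations a feature is selected
    when its cumulative relevance exceeds ``c * sqrt(n_f)`` standard
    deviations of the deltas, where ``n_f`` is its inclusion count — the
    threshold a symmetric random walk of ``n_f`` steps would cross with
    probability ~2.5 % (c = 1.96).

    Returns the selected feature names (or column indices when
    *feature_names* is None).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes")
    if counts.min() < k + 1:
        raise ValueError(f"need more than k+1={k + 1} samples per class")
    rng = np.random.default_rng(seed)

    def draw_split():
        dev = []
        for cls in classes:
            idx = np.nonzero(y == cls)[0]
            perm = rng.permutation(idx)
            n_dev = max(1, int(round(dev_fraction * len(idx))))
            dev.append(perm[:n_dev])
        dev = np.concatenate(dev)
        return np.setdiff1d(np.arange(n), dev), dev

    Xs = StandardScaler().fit_transform(X)

    relevance = np.zeros(p)
    inclusion = np.zeros(p, int)
    deltas = []
    uar_sum = 0.0
    for t in range(1, iterations + 1):
        train_idx, dev_idx = draw_split()
        subset = np.nonzero(rng.random(p) < subset_prob)[0]
        if subset.size == 0:
            subset = np.array([int(rng.integers(p))])
        knn = KNeighborsClassifier(n_neighbors=k)
        knn.fit(Xs[np.ix_(train_idx, subset)], y[train_idx])
        pred = knn.predict(Xs[np.ix_(dev_idx, subset)])
        recalls = [np.mean(pred[y[dev_idx] == cls] == cls) for cls in classes]
        uar = float(np.mean(recalls))
        uar_sum += uar
        delta = uar - uar_sum / t
        deltas.append(delta)
        relevance[subset] += delta
        inclusion[subset] += 1

    sd = float(np.std(deltas))
    if sd <= 0:
        return []
    threshold = c * np.sqrt(np.maximum(inclusion, 1)) * sd
    selected = np.nonzero(relevance > threshold)[0]
    if feature_names is not None:
        return [feature_names[i] for i in selected]
    return selected.tolist()


# --------------------------------------------------------------- undersampling


def undersample_near_boundary(X: np.ndarray, y: np.ndarray, ratio: int,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Keep all positives and the ``ratio * n_pos`` hardest negatives.

    Hardness = Euclidean distance (on z-scored features) to the nearest
    positive; ties broken by sample index.  If the quota exceeds the number
    of negatives, all samples are kept.
    """
    import logging

    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    X = np.asarray(X, float)
    y = np.asarray(y)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    quota = ratio * len(pos)
    if quota >= len(neg):
        if quota > len(neg):
            logging.getLogger(__name__).warning(
                "undersampling quota %d exceeds %d negatives; keeping all", quota, len(neg))
        return X, y
    Xs = StandardScaler().fit_transform(X)
    d = cdist(Xs[neg], Xs[pos]).min(axis=1)
    order = np.argsort(d, kind="stable")[:quota]
    keep = np.sort(np.concatenate([pos, neg[order]]))
    return X[keep], y[keep]


# --------------------------------------------------------------- WSVM


def train_wsvm(X: np.ndarray, y: np.ndarray, cost: float, gamma: float,
               class_weight: float | None = None) -> SVC:
    """RBF-kernel SVM with a positive-class misclassification weight.

    *class_weight* defaults to the residual imbalance ratio n_neg/n_pos of
    the training set, so minority errors cost proportionally more.  The
    returned model exposes ``decision_function`` scores for ROC analysis.
    """
    y = np.asarray(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one sample per class")
    if class_weight is None:
        class_weight = max(n_neg / n_pos, 1.0)
    model = SVC(C=cost, gamma=gamma, kernel="rbf", class_weight={1: class_weight, 0: 1.0})
    model.fit(np.asarray(X, float), y)
    return model


# --------------------------------------------------------------- two-layer CV

DEFAULT_COST_GRID = tuple(2.0 ** e for e in range(-1, 14))
DEFAULT_GAMMA_GRID = (2.0 ** -7, 2.0 ** -5, 2.0 ** -3, 2.0 ** -1, 1.0)


@dataclass
class CVConfig:
    """Grids and fold counts for the two-layer cross-validation."""

    K: int = 10
    L: int = 3
    cost_grid: tuple = DEFAULT_COST_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    ratio_grid: tuple | None = None  # None -> 1 .. imbalance ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2 or self.L < 2:
            raise ValueError("K and L must both be >= 2")
        if not self.cost_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")


@dataclass
class CVReport:
    gmean: float
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    fold_gmean: list = field(default_factory=list)
    fold_auc: list = field(default_factory=list)
    fold_sensitivity: list = field(default_factory=list)
    fold_specificity: list = field(default_factory=list)
    fold_accuracy: list = field(default_factory=list)
    chosen_params: list = field(default_factory=list)
    roc_points: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "gmean": self.gmean, "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "chosen_params": self.chosen_params,
        }


def _ratio_grid(config: CVConfig, y) -> list[int]:
    if config.ratio_grid is not None:
        return list(config.ratio_grid)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    imbalance = max(1, n_neg // max(n_pos, 1))
    return list(range(1, imbalance + 1))


def _fit_eval(X_tr, y_tr, X_te, y_te, ratio, cost, gamma):
    Xu, yu = undersample_near_boundary(X_tr, y_tr, ratio)
    scaler = StandardScaler().fit(Xu)
    model = train_wsvm(scaler.transform(Xu), yu, cost, gamma)
    pred = model.predict(scaler.transform(X_te))
    sens, spec = _rates(y_te, pred)
    scores = model.decision_function(scaler.transform(X_te))
    return sens, spec, pred, scores


def inner_grid_search(X: np.ndarray, y: np.ndarray, config: CVConfig,
                      ) -> tuple[int, float, float]:
    """Argmax of mean L-fold Gmean over the (ratio, cost, gamma) grid.

    Ties are broken toward the smallest cost, then gamma, then ratio.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    ratios = _ratio_grid(config, y)
    best = None
    for ratio in ratios:
        for cost in config.cost_grid:
            for gamma in config.gamma_grid:
                skf = StratifiedKFold(n_splits=config.L, shuffle=True,
                                      random_state=config.seed)
                gms = []
                for tr, te in skf.split(X, y):
                    try:
                        sens, spec, _, _ = _fit_eval(X[tr], y[tr], X[te], y[te],
                                                     ratio, cost, gamma)
                    except ValueError:
                        sens = spec = 0.0
                    gms.append(gmean(sens, spec))
                key = (np.mean(gms), -cost, -gamma, -ratio)
                if best is None or key > best[0]:
                    best = (key, (ratio, cost, gamma))
    return best[1]


def two_layer_cv(X: np.ndarray, y: np.ndarray, config: CVConfig) -> CVReport:
    """Outer-K / inner-L nested cross-validation.

    Each outer training portion is grid-searched with inner L-fold CV; the
    winning (ratio, cost, gamma) is retrained on the whole training portion
    and evaluated on the held-out fold.  Reports the five standard measures
    (Gmean, AUC, accuracy, sensitivity, specificity), averaged over folds.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need two classes")
    skf = StratifiedKFold(n_splits=config.K, shuffle=True, random_state=config.seed)
    report = CVReport(0, 0, 0, 0, 0)
    all_scores, all_true = [], []
    for tr, te in skf.split(X, y):
        if np.unique(y[te]).size < 2:
            raise ValueError("a fold lost one of the classes; reduce K")
        inner = CVConfig(K=config.K, L=config.L, cost_grid=config.cost_grid,
                         gamma_grid=config.gamma_grid, ratio_grid=config.ratio_grid,
                         seed=config.seed)
        ratio, cost, gamma_ = inner_grid_search(X[tr], y[tr], inner)
        sens, spec, pred, scores = _fit_eval(X[tr], y[tr], X[te], y[te],
                                             ratio, cost, gamma_)
        report.fold_sensitivity.append(sens)
        report.fold_specificity.append(spec)
        report.fold_gmean.append(gmean(sens, spec))
        report.fold_accuracy.append(float(np.mean(pred == y[te])))
        report.fold_auc.append(float(roc_auc_score(y[te], scores)))
        report.chosen_params.append({"ratio": ratio, "cost": cost, "gamma": gamma_})
        all_scores.append(scores)
        all_true.append(y[te])
    report.sensitivity = float(np.mean(report.fold_sensitivity))
    report.specificity = float(np.mean(report.fold_specificity))
    report.gmean = float(np.mean(report.fold_gmean))
    report.accuracy = float(np.mean(report.fold_accuracy))
    report.auc = float(np.mean(report.fold_auc))
    from nodulecad.evaluation import roc_auc as _roc

    _, roc_pts = _roc(np.concatenate(all_scores), np.concatenate(all_true))
    report.roc_points = roc_pts
    return report
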