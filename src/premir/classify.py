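"""Classifier training, hyperparameter tuning, and the evaluation suite.

Four classifier families are supported — SVM, random forest, logistic
regression and k-nearest neighbours — trained on scaled 93-feature vectors
with stratified 10-fold cross-validation, a randomized-then-coordinate-wise
grid tuning protocol, and a confusion-matrix metric suite (sensitivity,
specificity, accuracy, precision, F1, Matthews correlation, trapezoidal
ROC-AUC and step-sum AUPRC).

Published best-parameter presets for the 12 (algorithm x balancing-strategy)
combinations are available through :func:`tuned_presets`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .manifest import MANIFEST_VERSION

__all__ = [
    "HyperparamSpace",
    "TrainedModel",
    "EvalReport",
    "default_space",
    "make_estimator",
    "cross_validate",
    "tune",
    "train_model",
    "evaluate",
    "evaluate_scores",
    "metrics_from_counts",
    "roc_auc_trapezoid",
    "auprc_step",
    "predict",
    "tuned_presets",
]

ALGORITHMS = ("svm", "rf", "logr", "knn")


@dataclass(frozen=True)
class HyperparamSpace:
    """Per-algorithm discrete parameter grids.

    ``grids`` maps parameter name to the candidate values, listed from the
    simplest model to the most complex (ties during tuning resolve toward the
    earlier, simpler value).
    """

    algorithm: str
    grids: dict[str, list]

    def sample(self, n: int, rng: np.random.Generator) -> list[dict]:
        """n configurations sampled uniformly (with replacement) per axis."""
        configs = []
        for _ in range(n):
            configs.append(
                {k: v[rng.integers(len(v))] for k, v in self.grids.items()}
            )
        return configs


def default_space(algorithm: str) -> HyperparamSpace:
    """The search ranges used for tuning each algorithm.

    SVM: C in [0.25, 100], kernel in {linear, poly, rbf}, gamma in (0, 10];
    RF: 10-5000 trees, depth 5-100, bootstrap on/off, leaf 1-10, split 2-10;
    KNN: 1-50 neighbours over euclidean/manhattan/minkowski distances;
    LogR: C in [10, 100] over a newton-cg/lbfgs/liblinear solver set.
    """
    if algorithm == "svm":
        return HyperparamSpace(
            "svm",
            {
                "C": [0.25, 0.5, 1, 2, 6, 10, 25, 50, 100],
                "kernel": ["linear", "poly", "rbf"],
                "gamma": [0.001, 0.01, 0.1, 1.0, 10.0],
            },
        )
    if algorithm == "rf":
        return HyperparamSpace(
            "rf",
            {
                "n_estimators": [10, 30, 100, 400, 800, 1400, 1600, 3000, 5000],
                "max_depth": [5, 10, 30, 50, 100],
                "bootstrap": [True, False],
                "min_samples_leaf": [1, 2, 4, 10],
                "min_samples_split": [2, 5, 10],
            },
        )
    if algorithm == "knn":
        return HyperparamSpace(
            "knn",
            {
                "n_neighbors": [1, 2, 3, 5, 7, 11, 21, 35, 50],
                "metric": ["euclidean", "manhattan", "minkowski"],
            },
        )
    if algorithm == "logr":
        return HyperparamSpace(
            "logr",
            {
                "C": [10, 30, 50, 70, 100],
                "solver": ["newton-cg", "lbfgs", "liblinear"],
            },
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def make_estimator(algorithm: str, params: dict, seed: int = 0):
    """Instantiate a scikit-learn estimator for one of the four families.

    SVM probabilities use Platt-style calibration on training folds
    (``probability=True``); minkowski distance uses order p = 3.
    """
    if algorithm == "svm":
        from sklearn.calibration import CalibratedClassifierCV
        from sklearn.svm import SVC

        return CalibratedClassifierCV(
            SVC(random_state=seed, **params), method="sigmoid", ensemble=False
        )
    if algorithm == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "logr":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if algorithm == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        params = dict(params)
        if params.get("metric") == "minkowski":
            params.setdefault("p", 3)
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class TrainedModel:
    """A fitted classifier with its scaler and provenance."""

    algorithm: str
    params: dict
    estimator: Any
    scaler: Any = None
    manifest_version: str = MANIFEST_VERSION
    cv_score: float | None = None
    seed: int = 0

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        import joblib

        return joblib.load(path)


# ---------------------------------------------------------------------------
# Cross-validation and tuning
# ---------------------------------------------------------------------------


def cross_validate(
    algorithm: str,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Stratified k-fold mean accuracy; returns (mean, per-fold scores)."""
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"{folds}-fold CV needs >= {folds} rows per class "
            f"(smallest class has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X, y):
        est = make_estimator(algorithm, params, seed=seed)
        est.fit(X[train_idx], y[train_idx])
        scores.append(float((est.predict(X[test_idx]) == y[test_idx]).mean()))
    return float(np.mean(scores)), scores


@dataclass
class TuneResult:
    best_params: dict
    best_score: float
    trace: list[tuple[dict, float]] = field(default_factory=list)


def tune(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    space: HyperparamSpace | None = None,
    n_random: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> TuneResult:
    """Randomized search followed by coordinate-wise grid refinement.

    Stage 1 samples ``n_random`` configurations uniformly from the space and
    scores each by stratified k-fold mean accuracy. Stage 2 fixes the best
    configuration and sweeps one parameter at a time over its full grid,
    re-sweeping until no parameter changes. Ties resolve toward the simpler
    model (earlier grid entry: fewer trees, smaller C, fewer neighbours).
    """
    space = space or default_space(algorithm)
    rng = np.random.default_rng(seed)
    trace: list[tuple[dict, float]] = []
    cache: dict[tuple, float] = {}

    def score(params: dict) -> float:
        key = tuple(sorted(params.items()))
        if key not in cache:
            cache[key], _ = cross_validate(
                algorithm, params, X, y, folds=folds, seed=seed
            )
            trace.append((dict(params), cache[key]))
        return cache[key]

    configs = space.sample(n_random, rng)
    if not configs:
        configs = [{k: v[0] for k, v in space.grids.items()}]
    best = max(configs, key=score)
    best_score = score(best)

    changed = True
    while changed:
        changed = False
        for name, values in space.grids.items():
            for v in values:  # grid order = simplest first; strict > wins
                cand = {**best, name: v}
                if cand == best:
                    continue
                s = score(cand)
                if s > best_score:
                    best, best_score = cand, s
                    changed = True
    return TuneResult(best_params=best, best_score=best_score, trace=trace)


def train_model(
    algorithm: str,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    scaler=None,
    seed: int = 0,
    cv_score: float | None = None,
) -> TrainedModel:
    est = make_estimator(algorithm, params, seed=seed)
    est.fit(np.asarray(X, dtype=float), np.asarray(y))
    return TrainedModel(
        algorithm=algorithm,
        params=params,
        estimator=est,
        scaler=scaler,
        cv_score=cv_score,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts plus every derived metric for one test set.

    Zero-denominator metrics are 0 by convention (a degenerate classifier
    that never predicts positive has precision 0, not NaN).
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sn: float
    sp: float
    precision: float
    f1: float
    mcc: float
    auc: float | None = None
    auprc: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "acc": self.acc,
            "SN": self.sn,
            "SP": self.sp,
            "precision": self.precision,
            "F1": self.f1,
            "MCC": self.mcc,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        if self.auprc is not None:
            d["AUPRC"] = self.auprc
        return d


def _div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_counts(
    tp: int, tn: int, fp: int, fn: int, auc: float | None = None,
    auprc: float | None = None,
) -> EvalReport:
    """All confusion-matrix metrics from the four counts.

    SN = TP/(TP+FN), SP = TN/(TN+FP), Acc = (TP+TN)/total, p = TP/(TP+FP),
    F1 = 2·SN·p/(SN+p) and
    MCC = (TP·TN - FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    sn = _div(tp, tp + fn)
    sp = _div(tn, tn + fp)
    acc = _div(tp + tn, tp + tn + fp + fn)
    prec = _div(tp, tp + fp)
    f1 = _div(2 * sn * prec, sn + prec)
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        acc=acc, sn=sn, sp=sp, precision=prec, f1=f1, mcc=mcc,
        auc=auc, auprc=auprc,
    )


def _roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-swept (FPR, TPR) points from (0,0) to (1,1)."""
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    P = y.sum()
    N = len(y) - P
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep only the last point of each tied-score block
    last = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, tps[last] / P if P else np.zeros(len(last))]
    fpr = np.r_[0.0, fps[last] / N if N else np.zeros(len(last))]
    return fpr, tpr


def roc_auc_trapezoid(y_true, scores) -> float:
    """ROC-AUC by trapezoidal summation over threshold-swept points.

    With binary (0/1) scores the curve collapses to a single operating point
    and the area reduces to (SN + SP) / 2.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) != len(scores):
        raise ValueError("label/score length mismatch")
    fpr, tpr = _roc_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def auprc_step(y_true, scores) -> float:
    """Area under the precision-recall curve by the average-precision step sum:
    AP = sum_i (R_i - R_{i-1}) * P_i over descending score thresholds."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    P = y.sum()
    if P == 0:
        return 0.0
    tps = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    last = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    recall = np.r_[0.0, tps[last] / P]
    precision = np.r_[1.0, tps[last] / ranks[last]]
    return float(np.sum(np.diff(recall) * precision[1:]))


def evaluate_scores(y_true, scores, threshold: float = 0.5) -> EvalReport:
    """Full evaluation of continuous (or binary) scores against labels."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) != len(scores):
        raise ValueError("label/score length mismatch")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    return metrics_from_counts(
        tp, tn, fp, fn,
        auc=roc_auc_trapezoid(y_true, scores),
        auprc=auprc_step(y_true, scores),
    )


def _positive_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    proba = model.estimator.predict_proba(X)
    pos_col = list(model.estimator.classes_).index(1)
    return proba[:, pos_col]


def evaluate(
    model: TrainedModel, X_test: np.ndarray, y_test, *, prescaled: bool = False
) -> EvalReport:
    """Evaluate a trained model on a held-out test matrix at threshold 0.5."""
    X = np.asarray(X_test, dtype=float)
    if model.scaler is not None and not prescaled:
        X = model.scaler.transform(X)
    return evaluate_scores(np.asarray(y_test, dtype=int), _positive_scores(model, X))


def predict(
    model: TrainedModel,
    pairs,
    *,
    backend=None,
    zd_shuffles: int = 0,
    seed: int | None = None,
):
    """Predict (label, probability) for (record, structure) pairs, in order.

    Features are computed with the model's manifest; a manifest-version
    mismatch raises. Returns a list of (record_id, label, probability).
    """
    from .features import featurize
    from .manifest import default_manifest

    manifest = default_manifest()
    if manifest.version != model.manifest_version:
        raise ValueError(
            f"model expects manifest {model.manifest_version}, "
            f"package provides {manifest.version}"
        )
    rows = []
    ids = []
    for rec, st in pairs:
        fv = featurize(
            rec, st, backend=backend, zd_shuffles=zd_shuffles, seed=seed,
            manifest=manifest,
        )
        rows.append(fv.values)
        ids.append(rec.id)
    X = np.asarray(rows, dtype=float)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    probs = _positive_scores(model, X)
    return [
        (rid, int(p >= 0.5), float(p)) for rid, p in zip(ids, probs)
    ]


# ---------------------------------------------------------------------------
# Published parameter presets
# ---------------------------------------------------------------------------

_PRESETS: dict[str, tuple[str, dict]] = {
    # SMOTE-balanced training
    "svm_smote": ("svm", {"C": 10, "kernel": "rbf", "gamma": 0.01}),
    "rf_smote": ("rf", {"n_estimators": 1600, "max_depth": 30, "bootstrap": False,
                        "min_samples_leaf": 1, "min_samples_split": 2}),
    "logr_smote": ("logr", {"C": 70, "solver": "newton-cg"}),
    "knn_smote": ("knn", {"metric": "manhattan", "n_neighbors": 2}),
    # NearMiss-balanced training
    "svm_nm": ("svm", {"C": 1, "kernel": "rbf", "gamma": 0.001}),
    "rf_nm": ("rf", {"n_estimators": 1400, "max_depth": 30, "bootstrap": False,
                     "min_samples_leaf": 1, "min_samples_split": 2}),
    "logr_nm": ("logr", {"C": 100, "solver": "newton-cg"}),
    "knn_nm": ("knn", {"metric": "euclidean", "n_neighbors": 7}),
    # unbalanced training
    "svm_imbalance": ("svm", {"C": 6, "kernel": "rbf", "gamma": 0.001}),
    "rf_imbalance": ("rf", {"n_estimators": 30, "max_depth": 10, "bootstrap": False,
                            "min_samples_leaf": 2, "min_samples_split": 2}),
    "logr_imbalance": ("logr", {"C": 30, "solver": "newton-cg"}),
    "knn_imbalance": ("knn", {"metric": "euclidean", "n_neighbors": 7}),
}

#: The two models selected for deployment after validation.
_PRESETS["insect_svm"] = _PRESETS["svm_smote"]
_PRESETS["insect_rf"] = _PRESETS["rf_smote"]


def tuned_presets() -> dict[str, tuple[str, dict]]:
    """Best-performing parameter sets for every (algorithm, strategy) pair.

    Keys are ``<algo>_<strategy>`` (strategy in smote/nm/imbalance) plus the
    deployment aliases ``insect_svm`` and ``insect_rf``. Values are
    ``(algorithm, params)`` ready for :func:`make_estimator`.
    """
    return {k: (a, dict(p)) for k, (a, p) in _PRESETS.items()}
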