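"""Memory-outcome prediction from network-remodelling features.

Each animal contributes six features summarising how its coactivity network
reorganised between learning and recall (Jaccard, turnover, mean per-neuron
turnover index, training-edge survival, loss, and testing-edge gain). A
logistic model with an elastic-net penalty predicts the binary outcome
(forget = positive class) under leave-one-out cross-validation: every animal
is scored by a model fitted on the others, and the held-out probabilities
yield accuracy, a confusion matrix, the ROC curve, and its AUC — the
probability that a randomly chosen forgetting animal receives a higher
predicted forget-probability than a remembering one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "ClassifierReport",
    "assemble_features",
    "loocv_classify",
    "roc_points",
]

FEATURE_NAMES = (
    "jaccard",
    "turnover",
    "mean_per_neuron_ti",
    "survival_rate",
    "loss_rate",
    "gain_rate",
)

POSITIVE_CLASS = "forget"


@dataclass
class FeatureMatrix:
    """Animals-by-features matrix in the fixed six-column order."""

    animal_ids: list
    X: np.ndarray  # raw values, shape (n_animals, 6)
    y: np.ndarray  # 1 = forget (positive class), 0 = remember
    X_z: np.ndarray = None  # type: ignore[assignment]  # z-scored across animals
    degenerate_columns: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape != (len(self.animal_ids), len(FEATURE_NAMES)):
            raise ValueError("X must be n_animals x 6 in the fixed feature order")
        if np.any(np.isnan(self.X)):
            raise ValueError("feature matrix contains missing entries")
        if self.X_z is None:
            self.X_z, self.degenerate_columns = _zscore_columns(self.X)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)


def _zscore_columns(X: np.ndarray) -> tuple[np.ndarray, set]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = {FEATURE_NAMES[j] for j in np.nonzero(sd == 0)[0]}
    safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / safe, degenerate


def assemble_features(reports: dict, records: dict) -> FeatureMatrix:
    """Build the feature matrix from per-animal ComparisonReports and records.

    *reports* maps animal id -> training-vs-test ComparisonReport; *records*
    maps animal id -> AnimalRecord with a defined outcome. Any animal with a
    missing feature or label is rejected by name.
    """
    animal_ids = sorted(reports, key=str)
    rows, labels = [], []
    for aid in animal_ids:
        rep = reports[aid]
        if aid not in records or records[aid].outcome is None:
            raise ValueError(f"animal {aid!r} has no outcome label")
        vals = [
            rep.jaccard,
            rep.turnover,
            rep.mean_edge_turnover_ti,
            rep.survival_rate,
            rep.loss_rate,
            rep.gain_rate,
        ]
        for name, v in zip(FEATURE_NAMES, vals):
            if v is None:
                raise ValueError(f"animal {aid!r} is missing feature {name!r}")
        rows.append(vals)
        labels.append(1 if records[aid].outcome == POSITIVE_CLASS else 0)
    return FeatureMatrix(animal_ids=animal_ids, X=np.array(rows), y=np.array(labels))


@dataclass
class ClassifierReport:
    """Held-out LOOCV predictions and their summary metrics."""

    animal_ids: list
    probabilities: np.ndarray  # held-out P(forget) per animal
    scores: np.ndarray  # probability centred on the training fold's base rate (ROC input)
    y_true: np.ndarray
    y_pred: np.ndarray
    accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted (0, 1)
    roc: tuple  # (fpr, tpr, thresholds)
    auc: float
    fold_coefficients: list  # per-fold (intercept, coef vector)
    prior_folds: list = field(default_factory=list)  # folds that fell back to the class prior

    def __post_init__(self) -> None:
        if not np.all((self.probabilities >= 0) & (self.probabilities <= 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        n = len(self.y_true)
        if abs(self.accuracy - np.trace(self.confusion) / n) > 1e-12:
            raise ValueError("accuracy must equal trace(confusion)/n")

    def to_dict(self) -> dict:
        fpr, tpr, thr = self.roc
        return {
            "animal_ids": [str(a) for a in self.animal_ids],
            "probabilities": self.probabilities.tolist(),
            "scores": self.scores.tolist(),
            "y_true": self.y_true.tolist(),
            "y_pred": self.y_pred.tolist(),
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "auc": self.auc,
            "roc_fpr": np.asarray(fpr).tolist(),
            "roc_tpr": np.asarray(tpr).tolist(),
            "prior_folds": self.prior_folds,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def roc_points(probs: np.ndarray, y: np.ndarray) -> tuple[tuple, float]:
    """ROC curve over all thresholds and its trapezoidal AUC.

    The trapezoidal AUC over the full-threshold ROC equals the Mann-Whitney
    pair statistic: the probability (with ties counted half) that a positive
    scores above a negative.
    """
    probs = np.asarray(probs, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y, probs)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thr), auc


def _fit_fold(X: np.ndarray, y: np.ndarray, l1_ratio: float, reg_strength: float, seed: int):
    # class_weight="balanced" keeps the intercept from tracking the leave-one-out
    # fold's class imbalance, which would otherwise anti-rank null probabilities
    model = LogisticRegression(
        solver="saga",
        l1_ratio=l1_ratio,
        C=1.0 / reg_strength,
        max_iter=20000,
        tol=1e-7,
        random_state=seed,
        class_weight="balanced",
    )
    model.fit(X, y)
    return model


def loocv_classify(
    features: FeatureMatrix,
    l1_ratio: float = 0.5,
    reg_strength: float = 1.0,
    seed: int = 0,
    leakage_mode: str = "fold",
    penalized: bool = True,
) -> ClassifierReport:
    """Leave-one-out cross-validated elastic-net logistic classification.

    Each animal is held out in turn; the model is fitted on the remaining
    n - 1 and emits the held-out P(forget). ``leakage_mode='fold'`` (default)
    re-z-scores features on each training fold and applies the fold transform
    to the held-out animal, avoiding information leakage; ``'cohort'``
    z-scores once across all animals. Predicted label thresholds the
    probability at 0.5, ties resolved to remember (0). A training fold with a
    single class emits that fold's class prior and is flagged.

    The ROC pools scores from n differently-composed training folds. Raw
    pooled probabilities are pessimistically biased under a null (holding out
    a forget animal lowers the fold's forget share, and with it every null
    probability the fold emits), so the curve is computed on fold-centred
    scores — the held-out probability minus the training fold's observed base
    rate — with inverse-class-frequency weights in the fit. Under label
    permutations this pooled ROC is empirically unbiased (AUC ~ 0.5).
    """
    if features.n_animals < 4:
        raise ValueError("LOOCV needs at least 4 animals")
    if len(np.unique(features.y)) < 2:
        raise ValueError("both outcomes must be present in the cohort")
    if leakage_mode not in ("fold", "cohort"):
        raise ValueError("leakage_mode must be 'fold' or 'cohort'")
    X_all = features.X if leakage_mode == "fold" else features.X_z
    y = features.y
    n = features.n_animals
    probs = np.empty(n)
    scores = np.empty(n)
    fold_coefs: list = []
    prior_folds: list = []
    for k in range(n):
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        X_tr, y_tr = X_all[keep], y[keep]
        x_te = X_all[k]
        if leakage_mode == "fold":
            mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
            safe = np.where(sd == 0, 1.0, sd)
            X_tr = (X_tr - mu) / safe
            x_te = (x_te - mu) / safe
        if len(np.unique(y_tr)) < 2:
            probs[k] = float(y_tr.mean())
            scores[k] = 0.0
            prior_folds.append(k)
            fold_coefs.append((float("nan"), np.full(X_tr.shape[1], np.nan)))
            continue
        if penalized:
            model = _fit_fold(X_tr, y_tr, l1_ratio, reg_strength, seed)
        else:
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=20000, class_weight="balanced")
            model.fit(X_tr, y_tr)
        probs[k] = float(model.predict_proba(x_te[None, :])[0, list(model.classes_).index(1)])
        scores[k] = probs[k] - float(y_tr.mean())
        fold_coefs.append((float(model.intercept_[0]), model.coef_[0].copy()))
    y_pred = (probs > 0.5).astype(np.int64)  # ties at 0.5 predicted as remember
    confusion = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(y, y_pred):
        confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / n)
    roc, auc = roc_points(scores, y)
    return ClassifierReport(
        animal_ids=list(features.animal_ids),
        probabilities=probs,
        scores=scores,
        y_true=y.copy(),
        y_pred=y_pred,
        accuracy=accuracy,
        confusion=confusion,
        roc=roc,
        auc=auc,
        fold_coefficients=fold_coefs,
        prior_folds=prior_folds,
    )
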