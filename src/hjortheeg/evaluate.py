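"""Leave-one-subject-out evaluation with pluggable classifiers.

Each fold holds out every epoch of exactly one subject. Feature
standardization and mRMR selection are fitted on the training rows
only (mode ``per_fold``; a ``global`` mode that selects once on the
whole table is available to demonstrate the leakage-prone alternative).
Metrics are pooled over the epoch-level predictions of all folds, with
the patient class positive; subject-level majority-vote accuracy and
per-subject exact binomial significance against chance are reported
alongside.

Class-prior handling: LOSO training folds are inherently imbalanced
(one subject's class is short by one), which biases prior-sensitive
learners toward the over-represented class on uninformative data. The
margin learners therefore use balanced class weights and LDA uses
uniform priors; KNN is used as-is.
"""

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (
    ConfigurationError,
    FoldFailureError,
    UndefinedMetricError,
)
from .io import feature_columns_of
from .mrmr import SelectionConfig, SelectionResult, mrmr

POSITIVE = "patient"
NEGATIVE = "control"

#: learners that receive z-scored features (train-fold statistics)
_STANDARDIZED = {"linear_svm", "lda", "knn"}


@dataclass(frozen=True)
class ClassifierSpec:
    name: str = "linear_svm"  # {linear_svm, lda, knn, rf}
    hyperparameters: Dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        hp = self.hyperparameters
        if self.name == "linear_svm":
            return SVC(kernel="linear", C=hp.get("C", 1.0), class_weight="balanced")
        if self.name == "lda":
            return LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        if self.name == "knn":
            return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
        if self.name == "rf":
            return RandomForestClassifier(
                n_estimators=hp.get("n_trees", 500),
                random_state=self.seed,
                class_weight="balanced",
            )
        raise ConfigurationError(f"unknown classifier {self.name!r}")


@dataclass
class FoldResult:
    held_out_subject: str
    selection: SelectionResult
    y_true: np.ndarray  # boolean, True = patient
    y_pred: np.ndarray
    scores: np.ndarray  # continuous decision values, larger = more patient-like


@dataclass
class SubjectSignificance:
    subject: str
    group: str
    n_epochs: int
    n_correct: int
    p_value: float


@dataclass
class EvaluationReport:
    folds: List[FoldResult]
    confusion: Dict[str, int]  # TP/TN/FP/FN, patient positive
    accuracy: float  # percentages
    sensitivity: float
    specificity: float
    roc: np.ndarray  # (n, 2) array of (FPR, TPR)
    auc: float
    per_subject: List[SubjectSignificance]
    subject_accuracy: float  # majority-vote accuracy over subjects, percent

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "subject_accuracy": self.subject_accuracy,
            "roc": self.roc.tolist(),
            "per_subject": [
                {
                    "subject": s.subject,
                    "group": s.group,
                    "n_epochs": s.n_epochs,
                    "n_correct": s.n_correct,
                    "p_value": s.p_value,
                }
                for s in self.per_subject
            ],
            "folds": [
                {
                    "held_out_subject": f.held_out_subject,
                    "selected_features": f.selection.ordered,
                    "y_true": f.y_true.astype(int).tolist(),
                    "y_pred": f.y_pred.astype(int).tolist(),
                    "scores": f.scores.tolist(),
                }
                for f in self.folds
            ],
        }


def loso_folds(subject_ids: Sequence) -> List[Tuple[np.ndarray, np.ndarray]]:
    """One (train_rows, test_rows) pair per subject, in first-appearance order."""
    sids = np.asarray(subject_ids)
    order = pd.unique(sids)
    if len(order) < 2:
        raise ConfigurationError("LOSO needs at least 2 distinct subjects")
    folds = []
    for s in order:
        test = np.flatnonzero(sids == s)
        train = np.flatnonzero(sids != s)
        folds.append((train, test))
    return folds


def binomial_subject_test(n_correct: int, n_epochs: int, chance: float = 0.5) -> float:
    """Exact one-sided upper tail P(X >= n_correct), X ~ Binomial(n, chance)."""
    if not (0 < chance < 1):
        raise ConfigurationError("chance must lie in (0, 1)")
    if not (0 <= n_correct <= n_epochs):
        raise ConfigurationError("need 0 <= n_correct <= n_epochs")
    return float(spstats.binom.sf(n_correct - 1, n_epochs, chance))


def roc_auc(scores, labels) -> Tuple[np.ndarray, float]:
    """ROC points by threshold sweep and AUC as the Mann–Whitney statistic.

    ``labels`` is boolean (True = positive); ties in ``scores`` are
    handled by rank averaging, so AUC = U / (n+ · n−).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC/AUC needs both classes present")
    ranks = spstats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr]), auc


def _fit_predict_fold(
    table, features, train, test, clf_spec, sel_cfg, selection
) -> FoldResult:
    sid = str(table["subject_id"].iloc[test[0]])
    train_subj = set(table["subject_id"].iloc[train])
    if sid in train_subj:  # leakage guard: asserted, not assumed
        raise FoldFailureError(sid, "held-out subject present in training rows")
    y = (table["group"].to_numpy() == POSITIVE)
    if selection is None:
        selection = mrmr(table.iloc[train], table["group"].iloc[train], sel_cfg)
    X = table[selection.ordered].to_numpy(dtype=np.float64)
    Xtr, Xte = X[train], X[test]
    if clf_spec.name in _STANDARDIZED:
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    est = clf_spec.build()
    try:
        est.fit(Xtr, y[train])
        if hasattr(est, "decision_function"):
            scores = np.asarray(est.decision_function(Xte), dtype=np.float64)
        else:
            pos_col = list(est.classes_).index(True)
            scores = np.asarray(est.predict_proba(Xte)[:, pos_col], dtype=np.float64)
        pred = np.asarray(est.predict(Xte), dtype=bool)
    except Exception as exc:  # noqa: BLE001 — named-fold context per contract
        raise FoldFailureError(sid, exc) from exc
    return FoldResult(sid, selection, y[test], pred, scores)


def run_loso(
    table: pd.DataFrame,
    clf: ClassifierSpec = ClassifierSpec(),
    sel: Optional[SelectionConfig] = SelectionConfig(),
    mode: str = "per_fold",
) -> EvaluationReport:
    """LOSO-evaluate a labeled feature table.

    ``sel=None`` skips selection and uses every feature column.
    """
    if mode not in ("per_fold", "global"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    groups = set(table["group"])
    if not {POSITIVE, NEGATIVE} <= groups:
        raise ConfigurationError("table must contain both patient and control rows")
    features = feature_columns_of(table)
    global_sel = None
    if sel is None:
        global_sel = SelectionResult(list(features), [np.nan] * len(features),
                                     [np.nan] * len(features))
    elif mode == "global":
        global_sel = mrmr(table, table["group"], sel)
    folds = [
        _fit_predict_fold(table, features, train, test, clf, sel, global_sel)
        for train, test in loso_folds(table["subject_id"])
    ]
    y_true = np.concatenate([f.y_true for f in folds])
    y_pred = np.concatenate([f.y_pred for f in folds])
    scores = np.concatenate([f.scores for f in folds])
    tp = int(np.sum(y_pred & y_true))
    tn = int(np.sum(~y_pred & ~y_true))
    fp = int(np.sum(y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    total = tp + tn + fp + fn
    roc, auc = roc_auc(scores, y_true)
    per_subject = []
    votes_correct = 0
    for f in folds:
        n_corr = int(np.sum(f.y_pred == f.y_true))
        grp = POSITIVE if f.y_true[0] else NEGATIVE
        per_subject.append(
            SubjectSignificance(
                subject=f.held_out_subject,
                group=grp,
                n_epochs=len(f.y_true),
                n_correct=n_corr,
                p_value=binomial_subject_test(n_corr, len(f.y_true)),
            )
        )
        majority_patient = f.y_pred.mean() > 0.5
        votes_correct += int(majority_patient == bool(f.y_true[0]))
    return EvaluationReport(
        folds=folds,
        confusion={"TP": tp, "TN": tn, "FP": fp, "FN": fn},
        accuracy=100.0 * (tp + tn) / total,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        roc=roc,
        auc=auc,
        per_subject=per_subject,
        subject_accuracy=100.0 * votes_correct / len(folds),
    )
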