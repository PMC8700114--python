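"""CHF screening layer: group statistics, Fisher screening, cross-validated
classifiers, ROC/AUC, and the word-length x coarse-grain-scale sweep.

CHF is the positive class throughout: sensitivity is the fraction of CHF
records correctly flagged, specificity the fraction of normal records
correctly cleared.  Single-index screening uses a one-dimensional Fisher
discriminant (equal priors, pooled variance — in one dimension the decision
boundary is the midpoint of the two group means), evaluated in-sample.
Multi-feature screening uses stratified 5-fold cross-validation with
KNN (k=5), random forest and polynomial-kernel SVM, pooling held-out
predictions and scores over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .fapen import FapenConfig, fapen_ibs
from .io_rr import InsufficientDataError, IndexRecord, RRSeries

__all__ = [
    "ScreeningResult", "GroupTTestResult", "SweepResult",
    "group_ttest", "fisher_screen", "crossval_classify", "roc_auc",
    "parameter_sweep", "CLASSIFIERS",
]

ClassifierName = Literal["knn5", "rf", "svm_poly"]
CLASSIFIERS: tuple[str, ...] = ("knn5", "rf", "svm_poly")

POSITIVE = "chf"
NEGATIVE = "normal"


@dataclass(frozen=True)
class ScreeningResult:
    """Confusion counts, Acc/Sen/Spe in percent, and the pooled ROC."""

    tn: int
    tp: int
    fn: int
    fp: int
    roc_points: np.ndarray | None = None  # (k, 2) array of (FPR, TPR)
    auc: float = float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class GroupTTestResult:
    t: float
    p: float
    mean_normal: float
    sd_normal: float
    mean_chf: float
    sd_chf: float


def _split_groups(
    values: np.ndarray, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    return values[labels == NEGATIVE], values[labels == POSITIVE]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(tn, tp, fn, fp) with CHF positive."""
    pos = y_true == POSITIVE
    pred_pos = y_pred == POSITIVE
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    return tn, tp, fn, fp


def group_ttest(
    values: Sequence[float], labels: Sequence[str], *, equal_var: bool = False
) -> GroupTTestResult:
    """Two-sample t-test between the normal and CHF groups (Welch by default).

    Group summaries are reported as mean and (sample) SD.
    """
    normal, chf = _split_groups(np.asarray(values, dtype=float), labels)
    if normal.size < 2 or chf.size < 2:
        raise InsufficientDataError(
            f"t-test needs >= 2 records per group (normal={normal.size}, "
            f"chf={chf.size})"
        )
    res = stats.ttest_ind(normal, chf, equal_var=equal_var)
    return GroupTTestResult(
        t=float(res.statistic), p=float(res.pvalue),
        mean_normal=float(normal.mean()), sd_normal=float(normal.std(ddof=1)),
        mean_chf=float(chf.mean()), sd_chf=float(chf.std(ddof=1)),
    )


def fisher_screen(
    feature: Sequence[float], labels: Sequence[str]
) -> ScreeningResult:
    """One-dimensional Fisher-discriminant screen, evaluated in-sample.

    With equal priors and a pooled within-group variance the 1-D linear
    discriminant boundary reduces to the midpoint of the group means; a
    record falls in the group whose mean its value is nearer.  Decisions are
    therefore invariant under affine transforms a*x + b, a > 0.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    normal, chf = _split_groups(feature, labels)
    if normal.size == 0 or chf.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled_ss = (
        np.sum((normal - normal.mean()) ** 2) + np.sum((chf - chf.mean()) ** 2)
    )
    if pooled_ss == 0 and normal.mean() == chf.mean():
        raise ValueError("degenerate feature: identical for all records")
    threshold = 0.5 * (normal.mean() + chf.mean())
    if chf.mean() < normal.mean():
        pred_pos = feature < threshold
    else:
        pred_pos = feature > threshold
    y_pred = np.where(pred_pos, POSITIVE, NEGATIVE)
    tn, tp, fn, fp = _confusion(labels, y_pred)
    # score orientation: larger = more CHF-like
    scores = feature if chf.mean() > normal.mean() else -feature
    points, auc = roc_auc(scores, labels)
    return ScreeningResult(tn=tn, tp=tp, fn=fn, fp=fp, roc_points=points, auc=auc)


def _build_classifier(name: ClassifierName, seed: int):
    if name == "knn5":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "svm_poly":
        return SVC(kernel="poly", degree=3, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def crossval_classify(
    features: np.ndarray,
    labels: Sequence[str],
    classifier: ClassifierName = "rf",
    folds: int = 5,
    seed: int = 0,
) -> ScreeningResult:
    """Stratified k-fold CV; pooled confusion matrix and pooled-score ROC.

    Deterministic given ``seed`` (fold shuffling and any classifier
    randomness both derive from it).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if folds == y.size:  # leave-one-out; stratification is vacuous
        splitter = LeaveOneOut()
    else:
        for cls in (NEGATIVE, POSITIVE):
            if int(np.sum(y == cls)) < folds:
                raise ValueError(
                    f"class {cls!r} has fewer records than folds={folds}"
                )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    scores = np.empty(y.size, dtype=float)
    for train, test in splitter.split(X, y):
        model = _build_classifier(classifier, seed)
        model.fit(X[train], y[train])
        y_pred[test] = model.predict(X[test])
        if hasattr(model, "predict_proba"):
            proba = model.predict_proba(X[test])
            pos_col = list(model.classes_).index(POSITIVE)
            scores[test] = proba[:, pos_col]
        else:
            dec = model.decision_function(X[test])
            # decision_function is oriented towards classes_[1]
            scores[test] = dec if model.classes_[1] == POSITIVE else -dec
    tn, tp, fn, fp = _confusion(y, y_pred)
    points, auc = roc_auc(scores, y)
    return ScreeningResult(tn=tn, tp=tp, fn=fn, fp=fp, roc_points=points, auc=auc)


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[np.ndarray, float]:
    """ROC curve (FPR, TPR pairs) and trapezoidal AUC, CHF positive.

    AUC equals the Mann-Whitney statistic (ties at rank midpoint) and is
    invariant under strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("ROC/AUC undefined with a single class present")
    fpr, tpr, _ = roc_curve(y, scores, pos_label=POSITIVE)
    auc = float(roc_auc_score(y == POSITIVE, scores))
    return np.column_stack([fpr, tpr]), auc


@dataclass(frozen=True)
class SweepResult:
    """Fisher-screen accuracy of fApEn_IBS over the (m, s) parameter grid."""

    m_values: tuple[int, ...]
    s_values: tuple[int, ...]
    accuracy: np.ndarray  # (len(m_values), len(s_values)), nan = missing cell

    @property
    def argmax(self) -> tuple[int, int]:
        """(m, s) of the best cell (first by grid order among ties)."""
        flat = np.nanargmax(self.accuracy)
        i, j = np.unravel_index(flat, self.accuracy.shape)
        return self.m_values[i], self.s_values[j]


def parameter_sweep(
    records: Sequence[RRSeries],
    m_values: Sequence[int] = range(2, 7),
    s_values: Sequence[int] = range(1, 8),
    config: FapenConfig = FapenConfig(),
) -> SweepResult:
    """Recompute fApEn_IBS per record for every (m, s) cell and screen it.

    A cell where every record fails, or where screening is degenerate, is
    marked missing (nan) rather than fatal.
    """
    from .ibs import ibs_series
    from .preprocess import clean_rr, segment_minutes

    m_values = tuple(int(m) for m in m_values)
    s_values = tuple(int(s) for s in s_values)
    labels_all = [r.group for r in records]
    if any(g not in (POSITIVE, NEGATIVE) for g in labels_all):
        raise ValueError("parameter_sweep requires labelled (normal/chf) records")
    # cleaning/segmentation is (m, s)-independent: do it once per record
    segmented = []
    for rec in records:
        try:
            segmented.append((rec, segment_minutes(clean_rr(rec))))
        except InsufficientDataError:
            continue
    grid = np.full((len(m_values), len(s_values)), np.nan)
    for i, m in enumerate(m_values):
        for j, s in enumerate(s_values):
            values, labels = [], []
            for rec, segs in segmented:
                try:
                    series = ibs_series(segs, m=m, s=s)
                    values.append(
                        fapen_ibs(rec, config=config, precomputed_ibs=series)
                    )
                    labels.append(rec.group)
                except (InsufficientDataError, ValueError):
                    continue
            if not values:
                continue
            try:
                grid[i, j] = fisher_screen(values, labels).accuracy
            except (InsufficientDataError, ValueError):
                continue
    return SweepResult(m_values=m_values, s_values=s_values, accuracy=grid)
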