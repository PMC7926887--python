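"""Classifier configurations, cross-validation protocols and metrics.

Six classifier configurations are evaluated on the wavelet feature sets:
a two-hidden-layer MLP (50+50 nodes for the reduced P2 set, 90+90 for the
full P1 set), k-NN with k = 5, an unpruned Gini decision tree, a degree-3
polynomial-kernel SVM with C = 10, a 100-tree random forest, and bagging of
10 such SVMs. Features are min-max scaled to [0, 1] with the scaler fit on
the training portion only.

Two evaluation protocols:

* classic stratified 5-fold cross-validation;
* "partial blind" subject-wise cross-validation — one fold per subject
  index, training on the other subjects plus a small injected calibration
  subset (50 of 170 samples, ~29%) of each held-out subject's beats; the
  injected samples are excluded from testing.

Metrics are computed from the multi-class confusion matrix: accuracy
(trace/total), micro-F1 (identically equal to accuracy), Cohen's kappa
(p0 - pe)/(1 - pe) with marginal-product chance agreement, and macro-averaged
one-vs-rest ROC AUC. All metrics are reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .wavelet_features import FeatureMatrix

__all__ = [
    "ClassifierSpec",
    "ConfusionMatrix",
    "EvalResult",
    "PartialBlindPlan",
    "CLASSIFIER_KINDS",
    "build_estimator",
    "minmax_scale",
    "confusion",
    "accuracy_from_confusion",
    "kappa_from_confusion",
    "micro_f1_from_confusion",
    "auc_ovr",
    "run_5cv",
    "make_partial_blind_plan",
    "run_partial_blind",
]

CLASSIFIER_KINDS = ("ANN", "KNN", "DT", "SVM", "RF", "BAG")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the six classifier configurations.

    ``ann_width`` switches with the feature-set mode: 50 nodes per hidden
    layer for the reduced (P2) setting, 90 for the full (P1) setting.
    """

    kind: str
    seed: int = 0
    ann_width: int = 50
    knn_k: int = 5
    svm_degree: int = 3
    svm_c: float = 10.0
    rf_estimators: int = 100
    bag_estimators: int = 10

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    @classmethod
    def for_mode(cls, kind: str, mode: str = "P2", seed: int = 0) -> "ClassifierSpec":
        return cls(kind=kind, seed=seed, ann_width=90 if mode == "P1" else 50)


def build_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec."""
    if spec.kind == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=(spec.ann_width, spec.ann_width),
            max_iter=500,
            random_state=spec.seed,
        )
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.knn_k)
    if spec.kind == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=spec.seed)
    if spec.kind == "SVM":
        return SVC(
            kernel="poly",
            degree=spec.svm_degree,
            C=spec.svm_c,
            probability=True,
            random_state=spec.seed,
        )
    if spec.kind == "RF":
        return RandomForestClassifier(
            n_estimators=spec.rf_estimators, random_state=spec.seed
        )
    return BaggingClassifier(
        estimator=SVC(
            kernel="poly",
            degree=spec.svm_degree,
            C=spec.svm_c,
            probability=True,
            random_state=spec.seed,
        ),
        n_estimators=spec.bag_estimators,
        random_state=spec.seed,
    )


@dataclass
class ConfusionMatrix:
    """L x L contingency table; rows are actual classes, columns predicted."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.counts.shape[0]:
            raise ValueError("label count must match matrix size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalResult:
    """Per-fold metrics (percent) and the aggregate confusion matrix."""

    per_fold: list[dict[str, float]]
    aggregate_confusion: ConfusionMatrix
    mean_std: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean_std:
            keys = self.per_fold[0].keys() if self.per_fold else ()
            self.mean_std = {
                k: (
                    float(np.mean([f[k] for f in self.per_fold])),
                    float(np.std([f[k] for f in self.per_fold])),
                )
                for k in keys
            }

    @property
    def aggregate_accuracy(self) -> float:
        return accuracy_from_confusion(self.aggregate_confusion)


@dataclass
class PartialBlindPlan:
    """Index sets of the subject-wise folds.

    One fold per subject index; ``injected`` rows of the testing subjects
    are moved into training and never tested.
    """

    folds: list[dict[str, np.ndarray]]  # keys: train, test, injected

    def __post_init__(self) -> None:
        for f in self.folds:
            if np.intersect1d(f["injected"], f["test"]).size:
                raise ValueError("injected and tested samples must be disjoint")


def minmax_scale(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature [0, 1] scaling fit on the training matrix only.

    Constant training columns map to 0; test values outside the training
    range are not clipped.
    """
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    if train.shape[1] != test.shape[1]:
        raise ValueError("feature counts must match")
    scaler = MinMaxScaler().fit(train)
    return scaler.transform(train), scaler.transform(test)


def confusion(y_true, y_pred, label_order: tuple[str, ...]) -> ConfusionMatrix:
    """Counts[i][j] = number of instances with true class i predicted as j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    index = {lab: i for i, lab in enumerate(label_order)}
    counts = np.zeros((len(label_order), len(label_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label {t if t not in index else p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(label_order))


def accuracy_from_confusion(C: ConfusionMatrix) -> float:
    """Multi-class accuracy, percent: 100 * trace / total."""
    if C.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(C.counts)) / C.total


def kappa_from_confusion(C: ConfusionMatrix) -> float:
    """Cohen's kappa, percent, with marginal-product chance agreement.

    p0 = trace/total; pe = sum_i rowsum_i * colsum_i / total^2;
    kappa = (p0 - pe) / (1 - pe).
    """
    if C.total == 0:
        raise ValueError("empty confusion matrix")
    total = C.total
    p0 = np.trace(C.counts) / total
    pe = float(C.counts.sum(axis=1) @ C.counts.sum(axis=0)) / total**2
    if pe >= 1.0:
        raise ValueError("degenerate single-class matrix: chance agreement is 1")
    return 100.0 * (p0 - pe) / (1.0 - pe)


def micro_f1_from_confusion(C: ConfusionMatrix) -> float:
    """Micro-averaged F score, percent.

    Pooling the one-vs-rest counts over classes, every off-diagonal entry is
    simultaneously a false positive (of the predicted class) and a false
    negative (of the actual class), so micro-precision = micro-recall =
    micro-F1 = accuracy.
    """
    diag = np.diag(C.counts)
    tp = float(diag.sum())
    fp = float((C.counts.sum(axis=0) - diag).sum())
    fn = float((C.counts.sum(axis=1) - diag).sum())
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 100.0 * 2 * precision * recall / (precision + recall)


def auc_ovr(scores: np.ndarray, y_true, labels: tuple[str, ...]) -> float:
    """Macro-average of one-vs-rest ROC AUCs, percent.

    ``scores`` columns follow ``labels`` order; every class must appear in
    ``y_true``.
    """
    y_true = np.asarray(y_true)
    missing = set(labels) - set(y_true)
    if missing:
        raise ValueError(f"classes absent from y_true: {sorted(missing)}")
    index = {lab: i for i, lab in enumerate(labels)}
    y_idx = np.array([index[v] for v in y_true])
    return 100.0 * float(
        roc_auc_score(
            y_idx,
            scores,
            multi_class="ovr",
            average="macro",
            labels=np.arange(len(labels)),
        )
    )


def _fold_metrics(C: ConfusionMatrix, scores, y_true, labels) -> dict[str, float]:
    return {
        "accuracy": accuracy_from_confusion(C),
        "kappa": kappa_from_confusion(C),
        "auc": auc_ovr(scores, y_true, labels),
    }


def _fit_predict(estimator, F: FeatureMatrix, train_idx, test_idx, labels):
    X_train, X_test = minmax_scale(F.X[train_idx], F.X[test_idx])
    est = clone(estimator)
    est.fit(X_train, F.labels[train_idx])
    y_pred = est.predict(X_test)
    proba = est.predict_proba(X_test)
    # align probability columns with the requested label order
    order = [list(est.classes_).index(lab) for lab in labels]
    return y_pred, proba[:, order]


def run_5cv(F: FeatureMatrix, spec: ClassifierSpec, seed: int = 0) -> EvalResult:
    """Stratified 5-fold cross-validation; scaling fit per training fold."""
    labels = tuple(sorted(set(F.labels)))
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    counts = {lab: int(np.sum(F.labels == lab)) for lab in labels}
    if min(counts.values()) < 5:
        raise ValueError(f"every class needs >= 5 members, got {counts}")
    estimator = build_estimator(spec)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    per_fold = []
    agg = np.zeros((len(labels), len(labels)), dtype=int)
    for train_idx, test_idx in skf.split(F.X, F.labels):
        y_pred, proba = _fit_predict(estimator, F, train_idx, test_idx, labels)
        C = confusion(F.labels[test_idx], y_pred, labels)
        per_fold.append(_fold_metrics(C, proba, F.labels[test_idx], labels))
        agg += C.counts
    return EvalResult(
        per_fold=per_fold,
        aggregate_confusion=ConfusionMatrix(counts=agg, labels=labels),
    )


def make_partial_blind_plan(
    subjects: np.ndarray,
    labels: np.ndarray,
    inject_per_subject_class: int = 50,
    seed: int = 0,
) -> PartialBlindPlan:
    """Subject-wise folds with a small injected calibration subset.

    Subjects within each class are ordered by id; fold f holds out the f-th
    subject of every class, injecting the first ``inject_per_subject_class``
    rows of a seeded shuffle of each held-out subject-class cell into
    training and testing the remainder. Requires the same number of subjects
    per class and equal cell sizes.
    """
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    per_class_subjects = {
        c: sorted(set(subjects[labels == c])) for c in classes
    }
    n_subj = {c: len(s) for c, s in per_class_subjects.items()}
    if len(set(n_subj.values())) != 1:
        raise ValueError(f"unequal subjects per class: {n_subj}")
    cell_sizes = {
        (c, s): int(np.sum((labels == c) & (subjects == s)))
        for c in classes
        for s in per_class_subjects[c]
    }
    if len(set(cell_sizes.values())) != 1:
        raise ValueError(f"unequal subject-class cell sizes: {cell_sizes}")
    cell = next(iter(cell_sizes.values()))
    if inject_per_subject_class >= cell:
        raise ValueError(
            f"injection {inject_per_subject_class} must be below the cell size {cell}"
        )
    rng = np.random.default_rng(seed)
    n_folds = next(iter(n_subj.values()))
    folds = []
    for f in range(n_folds):
        test_subjects = {per_class_subjects[c][f] for c in classes}
        is_test_subject = np.isin(subjects, sorted(test_subjects))
        train = list(np.flatnonzero(~is_test_subject))
        injected, tested = [], []
        for c in classes:
            cell_idx = np.flatnonzero((labels == c) & (subjects == per_class_subjects[c][f]))
            perm = rng.permutation(len(cell_idx))
            injected.extend(cell_idx[perm[:inject_per_subject_class]])
            tested.extend(cell_idx[perm[inject_per_subject_class:]])
        folds.append(
            {
                "train": np.array(sorted(train + injected)),
                "test": np.array(sorted(tested)),
                "injected": np.array(sorted(injected)),
            }
        )
    return PartialBlindPlan(folds=folds)


def run_partial_blind(
    F: FeatureMatrix, spec: ClassifierSpec, plan: PartialBlindPlan
) -> EvalResult:
    """Evaluate a classifier under a partial-blind plan.

    Scaling is fit on each fold's training portion; the aggregate confusion
    covers the tested (non-injected) samples only.
    """
    n = F.n_instances
    for f in plan.folds:
        if max(int(f["train"].max()), int(f["test"].max())) >= n:
            raise ValueError("plan indices exceed the feature matrix size")
    labels = tuple(sorted(set(F.labels)))
    estimator = build_estimator(spec)
    per_fold = []
    agg = np.zeros((len(labels), len(labels)), dtype=int)
    for f in plan.folds:
        y_pred, proba = _fit_predict(estimator, F, f["train"], f["test"], labels)
        C = confusion(F.labels[f["test"]], y_pred, labels)
        per_fold.append(_fold_metrics(C, proba, F.labels[f["test"]], labels))
        agg += C.counts
    return EvalResult(
        per_fold=per_fold,
        aggregate_confusion=ConfusionMatrix(counts=agg, labels=labels),
    )
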