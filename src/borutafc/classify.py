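"""SVM classification of selected connections under leave-one-out CV.

An RBF-kernel support vector machine is trained on n-1 subjects and
predicts the held-out subject, for every subject in turn.  Per-feature
standardisation statistics come from the training fold only.  Because an
RBF machine has no primal weight vector, per-fold connection weights are
the pseudo-primal surrogate w = sum_i alpha_i y_i x_i over support vectors
(exact primal when kernel="linear"); fold weights are averaged into the
mean classification weights used by all downstream analytics.

Significance of the observed accuracy comes from a label-permutation test:
labels are redrawn, the full LOOCV repeated, and the add-one Monte-Carlo
p-value reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import SVC

from .connectome import FeatureTable

POSITIVE_LABEL = 1  # patients (ASD) are the positive class everywhere


@dataclass
class SvmConfig:
    """kernel "rbf" (default) or "linear"; C = 1; gamma "scale" = 1/(p*var);
    per-feature z-scoring with training-fold statistics unless disabled."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class FoldResult:
    held_out_subject: str
    true_label: int
    predicted_label: int
    decision_value: float
    weight_vector: np.ndarray


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    folds: list[FoldResult]
    mean_weights: np.ndarray
    config: SvmConfig = field(repr=False, default=None)
    permutation_null: np.ndarray | None = None
    p_value: float | None = None

    @property
    def predictions(self) -> np.ndarray:
        return np.array([f.predicted_label for f in self.folds])


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def extract_fold_weights(model: SVC, n_features: int | None = None) -> np.ndarray:
    """Pseudo-primal weight vector w = sum_i alpha_i y_i x_i of a fitted SVC.

    ``dual_coef_`` holds alpha_i * y_i; support vectors are rows of the
    (standardised) training matrix.  For a linear kernel this is the exact
    primal vector.
    """
    if not hasattr(model, "dual_coef_"):
        raise ValueError("model is not fitted")
    w = (model.dual_coef_ @ model.support_vectors_).ravel()
    if n_features is not None and w.size != n_features:
        raise ValueError("weight length mismatch")
    return w


def mean_classification_weights(folds: Sequence[FoldResult]) -> np.ndarray:
    """Elementwise mean of per-fold weight vectors."""
    if len(folds) == 0:
        raise ValueError("no folds")
    lengths = {f.weight_vector.size for f in folds}
    if len(lengths) != 1:
        raise ValueError("inconsistent weight vector lengths across folds")
    return np.mean([f.weight_vector for f in folds], axis=0)


def confusion_metrics(
    predictions: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as proportions.

    Sensitivity is the fraction of patients (+1) predicted positive;
    specificity the fraction of controls (-1) predicted negative.
    """
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    if pred.size == 0 or pred.shape != y.shape:
        raise ValueError("predictions and labels must be equal-length, nonempty")
    pos = y == POSITIVE_LABEL
    neg = ~pos
    tp = int(np.sum(pred[pos] == POSITIVE_LABEL))
    tn = int(np.sum(pred[neg] != POSITIVE_LABEL))
    accuracy = (tp + tn) / y.size
    sensitivity = tp / pos.sum() if pos.any() else np.nan
    specificity = tn / neg.sum() if neg.any() else np.nan
    return accuracy, sensitivity, specificity


def format_metrics_percent(
    accuracy: float, sensitivity: float, specificity: float
) -> tuple[float, float, float]:
    """Proportions as percentages rounded to one decimal (report convention)."""
    return tuple(round(float(100 * v), 1) for v in (accuracy, sensitivity, specificity))


def loocv_classify(
    table: FeatureTable, cfg: SvmConfig | None = None
) -> ClassificationReport:
    """Leave-one-out SVM classification of a (selected-feature) table."""
    cfg = cfg or SvmConfig()
    X = np.asarray(table.features, dtype=float)
    y = np.asarray(table.labels)
    report = _loocv_core(X, y, table.subjects, cfg)
    return report


def _loocv_core(
    X: np.ndarray, y: np.ndarray, subjects: Sequence[str], cfg: SvmConfig
) -> ClassificationReport:
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 subjects for LOOCV")
    if p < 1:
        raise ValueError("need at least one selected feature")
    if min(np.sum(y == 1), np.sum(y == -1)) < 2:
        raise ValueError("both classes need at least 2 members")
    folds: list[FoldResult] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, Xte = X[mask], X[~mask]
        ytr = y[mask]
        if np.unique(ytr).size < 2:
            raise ValueError("training fold has a single class")
        if cfg.standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        model = SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma)
        model.fit(Xtr, ytr)
        dec = float(model.decision_function(Xte)[0])
        pred = int(model.predict(Xte)[0])
        folds.append(
            FoldResult(
                held_out_subject=str(subjects[i]),
                true_label=int(y[i]),
                predicted_label=pred,
                decision_value=dec,
                weight_vector=extract_fold_weights(model, p),
            )
        )
    preds = np.array([f.predicted_label for f in folds])
    acc, sens, spec = confusion_metrics(preds, y)
    return ClassificationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        folds=folds,
        mean_weights=mean_classification_weights(folds),
        config=cfg,
    )


def permutation_test(
    table: FeatureTable,
    cfg: SvmConfig,
    n_perm: int,
    seed: int,
    observed_accuracy: float | None = None,
    select: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Label-permutation null for the LOOCV accuracy.

    Each permutation redraws the labels uniformly (class counts preserved),
    reruns the full LOOCV — and, in nested selection mode, first reruns the
    feature selection via ``select(X, y_perm) -> column indices`` — and
    records the null accuracy.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(table.features, dtype=float)
    y = np.asarray(table.labels)
    if observed_accuracy is None:
        if select is not None:
            cols = select(X, y)
            observed_accuracy = _loocv_core(X[:, cols], y, table.subjects, cfg).accuracy
        else:
            observed_accuracy = _loocv_core(X, y, table.subjects, cfg).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = y[rng.permutation(y.size)]
        if np.unique(y_perm).size < 2:  # cannot happen with permuted two-class y
            null[b] = np.nan
            continue
        Xb = X
        if select is not None:
            cols = select(X, y_perm)
            if len(cols) == 0:
                null[b] = max(np.mean(y_perm == 1), np.mean(y_perm == -1))
                continue
            Xb = X[:, cols]
        null[b] = _loocv_core(Xb, y_perm, table.subjects, cfg).accuracy
    p = (1 + int(np.sum(null >= observed_accuracy))) / (n_perm + 1)
    return p, null
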