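"""Forward-chaining cross-validation and the decoding metric suite.

Evaluation respects time: folds come from a forward-chaining split
(every test index strictly follows every train index of its fold, no
shuffling), features are standardized with training-fold statistics
only, and all metrics are computed exclusively on test segments.
Because classes are imbalanced, balanced accuracy (mean per-class
recall) is the headline metric, alongside accuracy, (macro-)F1, the
majority baseline and pooled confusion matrices.  Fold-mean +/- sd and
pooled-confusion views are both reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import ConfigError, DataError, DegenerateAnalysisError
from .features import WindowTable

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "forward_chain_splits",
    "standardize_per_fold",
    "balanced_accuracy",
    "f1_scores",
    "majority_baseline",
    "evaluate_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """Contiguous, time-ordered train/test splits (no shuffling)."""

    n_splits: int
    splits: tuple[tuple[np.ndarray, np.ndarray], ...]

    def __iter__(self):
        return iter(self.splits)


def forward_chain_splits(n_samples: int, n_splits: int = 5) -> FoldPlan:
    """Expanding-window time-series split.

    The tail of the series is partitioned into ``n_splits`` contiguous
    equal-sized test blocks (any remainder stays with the initial
    training segment); fold k trains on everything strictly before its
    test block.  Matches scikit-learn's TimeSeriesSplit.
    """
    if n_splits < 1:
        raise ConfigError("n_splits must be >= 1")
    if n_samples < n_splits + 1:
        raise DataError(
            f"{n_samples} samples cannot support {n_splits} forward-chaining folds"
        )
    test_size = n_samples // (n_splits + 1)
    first_test = n_samples - n_splits * test_size
    splits = []
    for k in range(n_splits):
        t0 = first_test + k * test_size
        train = np.arange(0, t0)
        test = np.arange(t0, t0 + test_size)
        assert train.max() < test.min()  # anti-leakage contract
        splits.append((train, test))
    return FoldPlan(n_splits=n_splits, splits=tuple(splits))


def standardize_per_fold(
    train_X: np.ndarray, test_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Column-wise z-scoring with training-fold statistics only.

    Constant training columns are centred but not scaled (divisor 1),
    with a logged warning.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if len(train_X) < 2:
        raise DataError("need >= 2 training rows to standardize")
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    const = sd == 0
    if const.any():
        log.warning(
            "constant training columns %s: centred but not scaled",
            np.flatnonzero(const).tolist(),
        )
        sd = np.where(const, 1.0, sd)
    return (train_X - mean) / sd, (test_X - mean) / sd, (mean, sd)


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean per-class recall; true classes with zero samples are excluded."""
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DataError("confusion matrix must be square")
    support = C.sum(axis=1)
    present = support > 0
    if not present.any():
        raise DegenerateAnalysisError("empty confusion matrix")
    if not present.all():
        log.warning(
            "classes %s have no true samples; excluded from balanced accuracy",
            np.flatnonzero(~present).tolist(),
        )
    recall = np.diag(C)[present] / support[present]
    return float(recall.mean())


def f1_scores(confusion: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class F1 (0 when precision + recall = 0) and macro average."""
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DataError("confusion matrix must be square")
    tp = np.diag(C)
    denom = C.sum(axis=1) + C.sum(axis=0)  # 2 TP + FN + FP
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    return f1, float(f1.mean())


def majority_baseline(class_counts: Sequence[int]) -> float:
    """Accuracy of always predicting the most frequent class."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise DataError("class counts must be nonempty with positive total")
    return float(counts.max() / counts.sum())


@dataclass
class MetricsReport:
    """Per-fold and pooled decoding metrics for one target."""

    target: str
    classes: list[int]
    fold_metrics: list[dict] = field(default_factory=list)
    skipped_folds: list[dict] = field(default_factory=list)
    pooled_confusion: np.ndarray | None = None

    # --- fold-mean view (headline numbers) ---
    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean([m["balanced_accuracy"] for m in self.fold_metrics]))

    @property
    def sd_balanced_accuracy(self) -> float:
        return float(np.std([m["balanced_accuracy"] for m in self.fold_metrics]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m["accuracy"] for m in self.fold_metrics]))

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean([m["macro_f1"] for m in self.fold_metrics]))

    # --- pooled-confusion view ---
    @property
    def pooled_balanced_accuracy(self) -> float:
        return balanced_accuracy(self.pooled_confusion)

    @property
    def pooled_macro_f1(self) -> float:
        return f1_scores(self.pooled_confusion)[1]

    @property
    def n_test(self) -> int:
        return int(self.pooled_confusion.sum())

    @property
    def majority_baseline_value(self) -> float:
        return majority_baseline(self.pooled_confusion.sum(axis=1))

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "classes": self.classes,
            "n_test": self.n_test,
            "n_folds_used": len(self.fold_metrics),
            "n_folds_skipped": len(self.skipped_folds),
            "mean_balanced_accuracy": round(self.mean_balanced_accuracy, 3),
            "sd_balanced_accuracy": round(self.sd_balanced_accuracy, 3),
            "mean_accuracy": round(self.mean_accuracy, 3),
            "mean_macro_f1": round(self.mean_macro_f1, 3),
            "pooled_balanced_accuracy": round(self.pooled_balanced_accuracy, 3),
            "pooled_macro_f1": round(self.pooled_macro_f1, 3),
            "majority_baseline": round(self.majority_baseline_value, 2),
            "pooled_confusion": self.pooled_confusion.astype(int).tolist(),
            "fold_metrics": self.fold_metrics,
            "skipped_folds": self.skipped_folds,
        }


def _targets_matrix(table: WindowTable, target: str) -> tuple[np.ndarray, list[int]]:
    if target == "v":
        return table.label_v[:, None], [0, 1]
    if target == "a":
        return table.label_a[:, None], [0, 1]
    if target == "q":
        return np.column_stack([table.label_v, table.label_a]), [0, 1, 2, 3]
    raise ConfigError(f"unknown target {target!r}; expected 'v', 'a' or 'q'")


def _to_classes(Y: np.ndarray, target: str) -> np.ndarray:
    if target == "q":
        return 2 * Y[:, 0] + Y[:, 1]
    return Y[:, 0]


def evaluate_pipeline(
    table: WindowTable,
    decoder_factory: Callable[[], object],
    target: str = "v",
    n_splits: int = 5,
    fold_plan: FoldPlan | None = None,
) -> MetricsReport:
    """Train/evaluate a decoder across forward-chaining folds.

    Per fold: standardize features with train statistics, fit a fresh
    decoder on the train block, predict the test block, and accumulate
    the confusion matrix.  Folds whose training targets are single-class
    (or otherwise degenerate) are skipped and logged.  Raises when every
    fold is skipped.
    """
    Y, classes = _targets_matrix(table, target)
    if np.unique(_to_classes(Y, target)).size < 2:
        raise DegenerateAnalysisError("fewer than 2 classes overall")
    plan = fold_plan or forward_chain_splits(len(table), n_splits)
    report = MetricsReport(target=target, classes=classes)
    pooled = np.zeros((len(classes), len(classes)))
    for k, (train, test) in enumerate(plan):
        if train.max() >= test.min():  # anti-leakage guard
            raise DataError(f"fold {k} leaks: train overlaps test")
        train_Z, test_Z, _ = standardize_per_fold(
            table.features[train], table.features[test]
        )
        try:
            decoder = decoder_factory()
            decoder.fit(train_Z, Y[train])
            pred = decoder.predict(test_Z)
        except DegenerateAnalysisError as exc:
            log.info("fold %d skipped: %s", k, exc)
            report.skipped_folds.append({"fold": k, "reason": str(exc)})
            continue
        y_true = _to_classes(Y[test], target)
        y_pred = _to_classes(np.atleast_2d(pred), target)
        C = _sk_confusion(y_true, y_pred, labels=classes)
        pooled += C
        f1_all, macro = f1_scores(C)
        report.fold_metrics.append(
            {
                "fold": k,
                "n_train": int(len(train)),
                "n_test": int(len(test)),
                "accuracy": float((y_true == y_pred).mean()),
                "balanced_accuracy": balanced_accuracy(C),
                "macro_f1": macro,
                "f1_per_class": f1_all.round(6).tolist(),
                "confusion": C.astype(int).tolist(),
            }
        )
    if not report.fold_metrics:
        raise DegenerateAnalysisError("every fold was skipped as degenerate")
    report.pooled_confusion = pooled
    return report
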