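"""Confusion matrices, one-vs-rest per-class metrics, and cross-validation.

Per-class metrics are derived from the multi-class confusion matrix by
one-vs-rest reduction: for class c, TP is the diagonal cell, FN the rest of
row c, FP the rest of column c, and TN everything else.  Six ratios are
computed per class:

* accuracy       (TP + TN) / (TP + TN + FP + FN)
* sensitivity    TP / (TP + FN)            (recall)
* specificity    TN / (TN + FP)
* precision      TP / (TP + FP)
* auc            (sensitivity + specificity) / 2   — balanced accuracy, the
  convention used throughout this package, *not* a ROC-curve area
* f_measure      harmonic mean of sensitivity and precision

Undefined ratios (zero denominators, e.g. a class absent from a fold) are
reported as NaN and flagged, never silently coerced to 0.  Rounding for table
display is round-half-even to 3 decimals applied at the final step only.

Cross-validation is stratified per class; the held-out predictions of all
folds are pooled into a single confusion matrix in which every sample is
counted exactly once, and the metrics are computed from that pooled matrix.
Note the default splits by image, not by user: consecutive sliding windows
overlap, so images from one recording can land in different folds.  Pass
``groups`` (e.g. user ids) to keep each group's images in a single fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from harimages.dcnn import DCNN, ModelConfig, TrainingConfig, build_model, predict, train

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "auc", "f_measure")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Multi-class confusion counts; rows = actual class, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.classes):
            raise ValueError("class list length must match the matrix size")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


class OvrCounts(NamedTuple):
    """One-vs-rest reduction of one class: TP, FP, FN, TN."""

    tp: int
    fp: int
    fn: int
    tn: int


def confusion(
    y_true: Sequence, y_pred: Sequence, classes: Sequence[str]
) -> ConfusionMatrix:
    """Tally the confusion matrix of predictions against ground truth."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            unknown = t if t not in index else p
            raise ValueError(f"label {unknown!r} is not in the class list")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def ovr_counts(cm: ConfusionMatrix, c: int | str) -> OvrCounts:
    """TP/FP/FN/TN of one class against the rest."""
    i = cm.classes.index(c) if isinstance(c, str) else int(c)
    if not 0 <= i < len(cm.classes):
        raise ValueError(f"class index {i} out of range")
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return OvrCounts(tp, fp, fn, tn)


@dataclass(frozen=True)
class ClassMetrics:
    """The six per-class ratios, at full precision; NaN entries are flagged."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float
    f_measure: float
    undefined: frozenset[str] = field(default=frozenset())

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Round-half-even for table display; NaN stays NaN."""
        return {
            k: (round(v, ndigits) if math.isfinite(v) else v)
            for k, v in self.as_dict().items()
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def class_metrics(cm: ConfusionMatrix, c: int | str) -> ClassMetrics:
    """Compute the six one-vs-rest metrics for one class (full precision)."""
    tp, fp, fn, tn = ovr_counts(cm, c)
    acc = _ratio(tp + tn, tp + tn + fp + fn)
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    auc = (sens + spec) / 2
    denom = sens + prec
    fmea = 2 * sens * prec / denom if math.isfinite(denom) and denom > 0 else math.nan
    metrics = ClassMetrics(
        acc, sens, spec, prec, auc, fmea,
        undefined=frozenset(
            name
            for name, v in zip(METRIC_NAMES, (acc, sens, spec, prec, auc, fmea))
            if not math.isfinite(v)
        ),
    )
    return metrics


@dataclass
class MetricsTable:
    """Per-class metrics with cross-class mean, sd and interval summaries.

    ``ci95`` is the normal-theory interval mean +/- 1.96 sd / sqrt(n_classes);
    ``band_sd`` is the cruder mean +/- sd band.  Both are reported because
    interval conventions for cross-class summaries vary between authors.
    """

    per_class: dict[str, ClassMetrics]
    mean: dict[str, float]
    sd: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    band_sd: dict[str, tuple[float, float]]

    def to_frame(self, ndigits: int | None = 3) -> pd.DataFrame:
        rows = {label: m.as_dict() for label, m in self.per_class.items()}
        rows["Mean"] = self.mean
        rows["st.d."] = self.sd
        frame = pd.DataFrame(rows).T[list(METRIC_NAMES)]
        return frame.round(ndigits) if ndigits is not None else frame


def summarize_metrics(per_class: dict[str, ClassMetrics]) -> MetricsTable:
    """Cross-class mean, sample sd and intervals for each metric."""
    if len(per_class) < 2:
        raise ValueError("need at least two classes to summarize")
    n = len(per_class)
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    ci95: dict[str, tuple[float, float]] = {}
    band: dict[str, tuple[float, float]] = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_class.values()])
        mu = float(np.mean(vals))
        sigma = float(np.std(vals, ddof=1))
        mean[name] = mu
        sd[name] = sigma
        half = 1.96 * sigma / math.sqrt(n)
        ci95[name] = (mu - half, mu + half)
        band[name] = (mu - sigma, mu + sigma)
    return MetricsTable(dict(per_class), mean, sd, ci95, band)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsTable:
    """All per-class metrics plus summaries, straight from a confusion matrix."""
    per_class = {label: class_metrics(cm, label) for label in cm.classes}
    return summarize_metrics(per_class)


def stratified_kfold(labels: Sequence, k: int, seed: int) -> np.ndarray:
    """Per-sample fold ids: within each class, fold sizes differ by at most 1.

    Shuffles within class with the given seed; deterministic.  Rejects any
    class with fewer than k samples, naming it.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    for cls, count in zip(classes, counts):
        if count < k:
            raise ValueError(
                f"class {cls!r} has only {count} samples, fewer than k={k} folds"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=np.int64)
    for fold_id, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        folds[test_idx] = fold_id
    return folds


def grouped_fold_assignment(groups: Sequence, k: int, seed: int) -> np.ndarray:
    """Fold ids that keep every group (e.g. user) inside a single fold."""
    g = np.asarray(groups)
    uniq = np.unique(g)
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} groups for k={k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    assignment = {grp: i % k for i, grp in enumerate(order)}
    return np.array([assignment[x] for x in g], dtype=np.int64)


@dataclass
class CrossValResult:
    """Pooled cross-validation outcome: one confusion matrix, one metrics table."""

    confusion: ConfusionMatrix
    metrics: MetricsTable
    fold_sizes: list[int]
    overall_accuracy: float


def cross_validate(
    images: np.ndarray,
    labels: np.ndarray,
    classes: Sequence[str],
    model_config: ModelConfig,
    training_config: TrainingConfig,
    k: int = 10,
    seed: int | None = None,
    groups: Sequence | None = None,
) -> CrossValResult:
    """Stratified k-fold cross-validation of the convolutional classifier.

    For each fold a fresh model is trained on the remaining k-1 folds (with a
    per-fold seed derived from the top-level one) and evaluated on the held-out
    fold; held-out predictions are pooled into a single confusion matrix.
    ``labels`` are integer class indices into ``classes``.
    """
    y = np.asarray(labels)
    if seed is None:
        seed = training_config.seed
    if groups is not None:
        folds = grouped_fold_assignment(groups, k, seed)
    else:
        folds = stratified_kfold(y, k, seed)
    n_classes = len(classes)
    pooled = np.zeros((n_classes, n_classes), dtype=np.int64)
    fold_sizes: list[int] = []
    for fold_id in range(k):
        test = folds == fold_id
        trn = ~test
        fold_seed = int(np.random.SeedSequence([seed, fold_id]).generate_state(1)[0]) % (2**31)
        model = build_model(model_config, class_names=classes)
        train(model, images[trn], y[trn], replace(training_config, seed=fold_seed))
        pred, _ = predict(model, images[test])
        np.add.at(pooled, (y[test], pred), 1)
        fold_sizes.append(int(test.sum()))
    cm = ConfusionMatrix(pooled, tuple(classes))
    overall = float(np.trace(pooled) / pooled.sum())
    return CrossValResult(cm, metrics_from_confusion(cm), fold_sizes, overall)
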