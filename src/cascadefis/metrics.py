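"""Multiclass confusion-matrix evaluation: micro / macro / weighted averages.

For an ``l``-class problem the confusion matrix ``C`` has rows indexed by the
true class and columns by the predicted class.  Per class ``i``::

    tp_i = C[i, i]
    fp_i = column i sum - tp_i
    fn_i = row i sum    - tp_i
    tn_i = total - tp_i - fp_i - fn_i

Micro averaging pools the counts before forming precision/recall; macro
averaging takes the unweighted mean of per-class scores; weighted averaging
weights per-class scores by class support (true-class row sums).  The
F-score generalises to ``F_beta = (beta^2 + 1) P R / (beta^2 P + R)``.

Average accuracy is the per-class mean of ``(tp_i + tn_i) / total`` — for
more than two classes it exceeds the overall accuracy because every correct
prediction also counts as a true negative for the other classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsConfig",
    "MetricsReport",
    "confusion",
    "micro_prf",
    "macro_prf",
    "weighted_prf",
    "average_accuracy",
    "overall_accuracy",
    "evaluate",
    "kfold_cv",
]


@dataclass
class ConfusionMatrix:
    """l x l count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        l = len(self.classes)
        if self.counts.shape != (l, l):
            raise ValueError("counts must be square over the class list")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fp - self.fn

    @property
    def support(self) -> np.ndarray:
        """Per-class number of true samples (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.classes,
                            columns=self.classes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.columns))


@dataclass(frozen=True)
class MetricsConfig:
    """beta weights recall against precision in the F-score;
    zero_division_value substitutes for 0/0 per-class ratios."""

    beta: float = 1.0
    zero_division_value: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be finite and > 0")


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Count matrix of true vs predicted labels."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if len(y_true) == 0:
        raise ValueError("need at least one sample")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=list(classes))


def _check_cm(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")


def _fbeta(p: float, r: float, beta: float, zero_value: float) -> float:
    denom = beta ** 2 * p + r
    if denom == 0:
        return zero_value
    return (beta ** 2 + 1) * p * r / denom


def micro_prf(cm: ConfusionMatrix,
              config: MetricsConfig = MetricsConfig()) -> tuple:
    """Pooled precision/recall/F: counts summed over classes first."""
    _check_cm(cm)
    tp, fp, fn = cm.tp.sum(), cm.fp.sum(), cm.fn.sum()
    z = config.zero_division_value
    p = tp / (tp + fp) if tp + fp > 0 else z
    r = tp / (tp + fn) if tp + fn > 0 else z
    return float(p), float(r), float(_fbeta(p, r, config.beta, z))


def _per_class_pr(cm: ConfusionMatrix, zero_value: float):
    tp, fp, fn = cm.tp, cm.fp, cm.fn
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), zero_value)
        r = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), zero_value)
    return p.astype(float), r.astype(float)


def macro_prf(cm: ConfusionMatrix,
              config: MetricsConfig = MetricsConfig()) -> tuple:
    """Unweighted per-class mean of precision/recall; F from the means."""
    _check_cm(cm)
    p, r = _per_class_pr(cm, config.zero_division_value)
    pm, rm = float(p.mean()), float(r.mean())
    return pm, rm, float(_fbeta(pm, rm, config.beta,
                                config.zero_division_value))


def weighted_prf(cm: ConfusionMatrix,
                 config: MetricsConfig = MetricsConfig()) -> tuple:
    """Support-weighted per-class precision/recall/F (weights = row sums)."""
    _check_cm(cm)
    p, r = _per_class_pr(cm, config.zero_division_value)
    w = cm.support.astype(float)
    f = np.array([_fbeta(pi, ri, config.beta, config.zero_division_value)
                  for pi, ri in zip(p, r)])
    # divide once so a perfect classifier scores exactly 1.0
    total = cm.total
    return float(w @ p / total), float(w @ r / total), float(w @ f / total)


def average_accuracy(cm: ConfusionMatrix) -> float:
    """Per-class mean of (tp_i + tn_i) / total."""
    _check_cm(cm)
    acc = (cm.tp + cm.tn) / cm.total
    return float(acc.mean())


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples (trace / total)."""
    _check_cm(cm)
    return float(cm.tp.sum() / cm.total)


@dataclass
class MetricsReport:
    """The full evaluation table: accuracy plus P/R/F under the three
    averaging conventions."""

    average_accuracy: float
    overall_accuracy: float
    precision_micro: float
    recall_micro: float
    fscore_micro: float
    precision_macro: float
    recall_macro: float
    fscore_macro: float
    precision_weighted: float
    recall_weighted: float
    fscore_weighted: float
    n_samples: int = 0
    n_classes: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        return cls(**json.loads(s))

    def summary(self) -> str:
        rows = [
            ("Average Accuracy", self.average_accuracy),
            ("Overall Accuracy", self.overall_accuracy),
            ("Precision (micro)", self.precision_micro),
            ("Recall (micro)", self.recall_micro),
            ("FScore (micro)", self.fscore_micro),
            ("Precision (macro)", self.precision_macro),
            ("Recall (macro)", self.recall_macro),
            ("FScore (macro)", self.fscore_macro),
            ("Precision (weighted)", self.precision_weighted),
            ("Recall (weighted)", self.recall_weighted),
            ("FScore (weighted)", self.fscore_weighted),
        ]
        width = max(len(name) for name, _ in rows)
        lines = ["Classification performance", "=" * (width + 9)]
        lines += [f"{name:<{width}}  {v:.4f}" for name, v in rows]
        lines.append(f"(n = {self.n_samples}, classes = {self.n_classes})")
        return "\n".join(lines)


def evaluate(y_true, y_pred, classes=None,
             config: MetricsConfig = MetricsConfig()) -> MetricsReport:
    """Build the confusion matrix and the full metrics report in one call."""
    cm = confusion(y_true, y_pred, classes)
    p_mi, r_mi, f_mi = micro_prf(cm, config)
    p_ma, r_ma, f_ma = macro_prf(cm, config)
    p_w, r_w, f_w = weighted_prf(cm, config)
    return MetricsReport(
        average_accuracy=average_accuracy(cm),
        overall_accuracy=overall_accuracy(cm),
        precision_micro=p_mi, recall_micro=r_mi, fscore_micro=f_mi,
        precision_macro=p_ma, recall_macro=r_ma, fscore_macro=f_ma,
        precision_weighted=p_w, recall_weighted=r_w, fscore_weighted=f_w,
        n_samples=cm.total, n_classes=len(cm.classes),
    )


def kfold_cv(y, trainer, evaluator, k: int = 10, seed: int = 0,
             stratified: bool = True):
    """Stratified k-fold cross-validation over sample indices.

    ``trainer(train_idx)`` must return a fitted model;
    ``evaluator(model, test_idx)`` must return a scalar accuracy.  Fold
    assignment is deterministic for a fixed seed.  Returns
    ``(fold_accuracies, mean)``.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples {n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                "every class needs >= k samples for stratified folds "
                "(pass stratified=False otherwise)"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in splitter.split(np.zeros(n), y):
        model = trainer(train_idx)
        accs.append(float(evaluator(model, test_idx)))
    accs = np.asarray(accs)
    return accs, float(accs.mean())
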