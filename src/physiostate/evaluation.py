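"""Confusion matrix, accuracy, F1 and Cohen's kappa for the binary
physiological-status task, plus train/test orchestration.

C1 (awake / waiting to sleep) is the positive class: TP counts cases truly
C1 predicted C1, FP cases truly C2 predicted C1.  Kappa corrects accuracy
for the agreement expected by chance, estimated from the confusion-matrix
marginals:

    p_c = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / n^2
    kappa = (ACC - p_c) / (1 - p_c)

Kappa is undefined (NaN) when p_c = 1, which only happens for degenerate
single-cell tables.  Zero-denominator precision/recall/F1 are reported as 0
with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .exceptions import ConfigError, DataFormatError
from .features import VALID_LABELS, FeatureTable

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "accuracy",
    "f1",
    "kappa",
    "evaluate_split",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with C1 as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigError("confusion counts must be non-negative")
        if self.total == 0:
            raise ConfigError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred, positive: str = "C1") -> ConfusionMatrix:
    """Tally the confusion matrix; labels must be C1/C2."""
    y_true = np.asarray(y_true, dtype=object).ravel()
    y_pred = np.asarray(y_pred, dtype=object).ravel()
    if y_true.size != y_pred.size:
        raise DataFormatError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    bad = (set(y_true) | set(y_pred)) - set(VALID_LABELS)
    if bad:
        raise DataFormatError(f"labels outside {VALID_LABELS}: {sorted(map(str, bad))}")
    if positive not in VALID_LABELS:
        raise ConfigError(f"positive class must be one of {VALID_LABELS}")
    t_pos = y_true == positive
    p_pos = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(t_pos & p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / n."""
    return (cm.tp + cm.tn) / cm.total


def _precision_recall(cm: ConfusionMatrix) -> tuple[float, float]:
    if cm.tp + cm.fp == 0:
        log.warning("no positive predictions; precision reported as 0")
        pre = 0.0
    else:
        pre = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        log.warning("no positive cases; recall reported as 0")
        rec = 0.0
    else:
        rec = cm.tp / (cm.tp + cm.fn)
    return pre, rec


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    pre, rec = _precision_recall(cm)
    if pre + rec == 0:
        return 0.0
    return 2 * pre * rec / (pre + rec)


def chance_agreement(cm: ConfusionMatrix) -> float:
    """p_c from the row/column marginal products."""
    n = cm.total
    return ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / (n * n)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa (ACC - p_c) / (1 - p_c); NaN when p_c = 1."""
    p_c = chance_agreement(cm)
    if p_c == 1.0:
        log.warning("chance agreement is 1; kappa undefined")
        return math.nan
    return (accuracy(cm) - p_c) / (1.0 - p_c)


@dataclass
class EvalReport:
    """Held-out evaluation: the three headline metrics plus context."""

    acc: float
    precision: float
    recall: float
    f1: float
    kappa: float
    p_c: float
    cm: ConfusionMatrix
    split: str
    seed: int

    def summary(self) -> str:
        lines = [
            f"split: {self.split} (seed {self.seed})",
            f"confusion (C1 positive): TP={self.cm.tp} FN={self.cm.fn} FP={self.cm.fp} TN={self.cm.tn}",
            f"accuracy : {self.acc:.4f}",
            f"precision: {self.precision:.4f}",
            f"recall   : {self.recall:.4f}",
            f"F1       : {self.f1:.4f}",
            f"kappa    : {self.kappa:.4f} (p_c={self.p_c:.4f})",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric,value\n")
            for k, v in [
                ("accuracy", self.acc),
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
                ("kappa", self.kappa),
                ("p_c", self.p_c),
                ("tp", self.cm.tp),
                ("fn", self.cm.fn),
                ("fp", self.cm.fp),
                ("tn", self.cm.tn),
            ]:
                fh.write(f"{k},{v:.12g}\n" if isinstance(v, float) else f"{k},{v}\n")


def report_from_labels(y_true, y_pred, split: str = "", seed: int = 0) -> EvalReport:
    cm = confusion(y_true, y_pred)
    pre, rec = _precision_recall(cm)
    return EvalReport(
        acc=accuracy(cm),
        precision=pre,
        recall=rec,
        f1=f1(cm),
        kappa=kappa(cm),
        p_c=chance_agreement(cm),
        cm=cm,
        split=split,
        seed=seed,
    )


def evaluate_split(
    table: FeatureTable,
    selected: list[str] | None,
    c: float,
    g: float,
    train_frac: float = 0.7,
    test_frac: float = 0.2,
    seed: int = 0,
) -> EvalReport:
    """Fit an RBF-SVM on a stratified train fraction, report metrics on a
    disjoint stratified test fraction; any remainder is unused.
    """
    if not (0 < train_frac < 1 and 0 < test_frac < 1 and train_frac + test_frac <= 1):
        raise ConfigError(f"invalid split fractions {train_frac}/{test_frac}")
    cols = selected if selected else table.feature_names
    x = table.features[cols].to_numpy(dtype=float)
    y = table.labels.to_numpy(dtype=object)
    idx = np.arange(len(y))
    train_idx, rest_idx = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed
    )
    rest_frac = 1.0 - train_frac
    if math.isclose(test_frac, rest_frac, rel_tol=1e-9):
        test_idx = rest_idx
    else:
        test_idx, _ = train_test_split(
            rest_idx,
            train_size=test_frac / rest_frac,
            stratify=y[rest_idx],
            random_state=seed,
        )
    for part, name in ((train_idx, "train"), (test_idx, "test")):
        if np.unique(y[part]).size < 2:
            raise DataFormatError(f"{name} partition lost a class; enlarge the split")
    clf = SVC(C=c, gamma=g, kernel="rbf")
    clf.fit(x[train_idx], y[train_idx])
    y_pred = clf.predict(x[test_idx])
    return report_from_labels(
        y[test_idx], y_pred, split=f"train={train_frac:g}/test={test_frac:g}", seed=seed
    )
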