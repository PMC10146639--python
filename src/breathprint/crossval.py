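"""Leave-one-out double cross-validation and the CVA statistic.

"Double" means the *entire* pipeline — autoscaling, principal-component
reduction and the canonical discriminant — is refit inside every held-out
fold; no projection is ever learned from the test sample.  With cohorts of
around eleven subjects this is the only defensible fold structure, and it is
what the offline recomputation of the instrument's cross-validation figure
amounts to.

The cross-validation accuracy (CVA) is reported as a percentage *truncated*
(not rounded) to two decimals: 7/11 correct prints as 63.63, 8/11 as 72.72.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone

from .containers import BreathPrintSet
from .discriminate import PCACanonicalDiscriminant

__all__ = ["FoldPrediction", "CVResult", "loo_cross_validate", "format_cva"]


@dataclass(frozen=True)
class FoldPrediction:
    sample_id: str
    true_label: str
    predicted_label: str
    canonical_score: float

    @property
    def correct(self) -> bool:
        return self.true_label == self.predicted_label


@dataclass(frozen=True)
class CVResult:
    per_fold: tuple[FoldPrediction, ...]
    n_correct: int
    n_total: int
    cva_percent: float
    per_class_accuracy: dict

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(self.per_class_accuracy)


def format_cva(n_correct: int, n_total: int) -> float:
    """Percent correct, truncated (floored) to two decimals.

    ``format_cva(7, 11) == 63.63`` — rounding would give 63.64.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    # integer arithmetic so truncation is exact for every k/n
    return (10000 * int(n_correct) // int(n_total)) / 100.0


def loo_cross_validate(
    prints: BreathPrintSet,
    n_pc: int = 4,
    estimator: PCACanonicalDiscriminant | None = None,
) -> CVResult:
    """Leave-one-out CV refitting the full reduction + discriminant per fold.

    Every fold clones a fresh estimator and fits it on all samples except the
    held-out one; there is deliberately no entry point for reusing a
    projection computed on the full data.
    """
    n = len(prints)
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out cross-validation")
    mask = prints.common_mask
    X = prints.X[:, mask]
    y = prints.y
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError(f"exactly 2 classes required; got {labels.tolist()}")
    base = estimator if estimator is not None else PCACanonicalDiscriminant(n_pc=n_pc)

    folds: list[FoldPrediction] = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        train_classes = np.unique(y[train])
        if train_classes.size < 2:
            raise ValueError(
                f"fold holding out sample {prints[i].sample_id!r} leaves a single-class "
                "training set"
            )
        est = clone(base).fit(X[train], y[train])
        pred = str(est.predict(X[i : i + 1])[0])
        score = float(est.canonical_scores(X[i : i + 1])[0])
        folds.append(FoldPrediction(prints[i].sample_id, str(y[i]), pred, score))

    n_correct = sum(f.correct for f in folds)
    per_class = {}
    for lab in labels:
        sel = [f for f in folds if f.true_label == str(lab)]
        per_class[str(lab)] = sum(f.correct for f in sel) / len(sel)
    return CVResult(
        per_fold=tuple(folds),
        n_correct=n_correct,
        n_total=n,
        cva_percent=format_cva(n_correct, n),
        per_class_accuracy=per_class,
    )
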