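"""Offline evaluation protocol: repeated ten-fold CV and comparison stats.

The offline protocol divides the 240 labelled trials into ten folds and
trains on nine while testing on the tenth, rotating through all folds;
the whole partition is redrawn four times, for 40 folds in total.  Folds
are stratified by class (6 test trials per class per fold at defaults).
Feature standardization is fit on the training folds only.

``paired_t_test`` and ``one_way_anova`` are thin, degenerate-case-safe
wrappers over the classical statistics used to compare feature sets and
optimizers; ``regression_performance`` is the Pearson correlation between
concatenated network outputs and their bit targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .features import FeatureScaler
from .lmbp import (
    LabelCodec,
    NetworkLayout,
    TrainingConfig,
    init_network,
    predict,
    train_adam,
    train_lmbp,
)
from .synth_emg import ActionClass

__all__ = [
    "CvResult",
    "FoldRecord",
    "repeated_kfold",
    "regression_performance",
    "paired_t_test",
    "one_way_anova",
]

#: Default training budget for cross-validation folds.  On separable data
#: LM converges well before the cap via the step-norm tolerance.
CV_TRAINING_CONFIG = TrainingConfig(max_epochs=100)


@dataclass
class FoldRecord:
    """Bookkeeping for one CV fold."""

    repeat: int
    fold: int
    test_indices: np.ndarray
    accuracy: float              # percent
    scaler_mean: np.ndarray      # standardization mean, fit on train rows only


@dataclass
class CvResult:
    """Aggregate of a repeated k-fold cross-validation run."""

    fold_accuracies: np.ndarray  # percent, one per fold across all repeats
    confusion: pd.DataFrame      # rows = true class, columns = predicted
    folds: list[FoldRecord] = field(default_factory=list)
    k: int = 10
    repeats: int = 4
    trainer: str = "lmbp"

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for cls in self.confusion.index:
            row = self.confusion.loc[cls]
            total = row.sum()
            out[cls] = 100.0 * row[cls] / total if total else float("nan")
        return out

    def summary(self) -> str:
        return (
            f"{self.trainer} {self.k}-fold x {self.repeats}: "
            f"{self.mean:.2f} +/- {self.std:.2f} % "
            f"(std over {len(self.fold_accuracies)} folds)"
        )


def _normalize_labels(labels) -> np.ndarray:
    return np.array([ActionClass.coerce(a) for a in labels], dtype=object)


def repeated_kfold(
    features,
    labels,
    k: int = 10,
    repeats: int = 4,
    trainer: str = "lmbp",
    seed: int = 0,
    config: TrainingConfig | None = None,
    n_hidden: int = 16,
) -> CvResult:
    """Repeated stratified k-fold cross-validation of the decoder.

    For each repeat a fresh random stratified partition is drawn; for each
    fold the feature scaler and the network are fit on the training nine
    tenths and accuracy is measured on the held-out tenth.  Fully seeded:
    partitioning and weight initialization both derive from ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = _normalize_labels(labels)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and labels disagree on sample count")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if trainer not in ("lmbp", "adam"):
        raise ValueError(f"unknown trainer {trainer!r}")
    config = config or CV_TRAINING_CONFIG
    train_fn = train_lmbp if trainer == "lmbp" else train_adam
    layout = NetworkLayout(n_input=X.shape[1], n_hidden=n_hidden, n_output=2)

    classes = list(ActionClass)
    class_names = [c.value for c in classes]
    confusion = pd.DataFrame(
        np.zeros((len(classes), len(classes)), dtype=int),
        index=class_names,
        columns=class_names,
    )
    y_str = np.array([a.value for a in y])

    ss = np.random.SeedSequence(seed)
    fold_accs: list[float] = []
    folds: list[FoldRecord] = []
    for r in range(repeats):
        split_child, init_child = ss.spawn(2)
        split_seed = int(split_child.generate_state(1, np.uint32)[0] % (2**31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
        init_seeds = init_child.generate_state(k, np.uint32)
        for f, (train_idx, test_idx) in enumerate(skf.split(X, y_str)):
            scaler = FeatureScaler().fit(X[train_idx])
            Xtr = scaler.transform(X[train_idx])
            Xte = scaler.transform(X[test_idx])
            Ytr = LabelCodec.encode(y[train_idx])
            net = init_network(layout, seed=int(init_seeds[f]))
            net, _ = train_fn(net, Xtr, Ytr, config)
            pred = predict(net, Xte)
            truth = y[test_idx]
            correct = sum(p is t for p, t in zip(pred, truth))
            acc = 100.0 * correct / len(test_idx)
            fold_accs.append(acc)
            folds.append(
                FoldRecord(
                    repeat=r,
                    fold=f,
                    test_indices=np.asarray(test_idx),
                    accuracy=acc,
                    scaler_mean=scaler.mean_.copy(),
                )
            )
            for p, t in zip(pred, truth):
                confusion.loc[t.value, p.value] += 1

    return CvResult(
        fold_accuracies=np.asarray(fold_accs),
        confusion=confusion,
        folds=folds,
        k=k,
        repeats=repeats,
        trainer=trainer,
    )


def regression_performance(outputs, targets) -> float:
    """Pearson correlation between flattened outputs and bit targets."""
    o = np.asarray(outputs, dtype=float).ravel()
    t = np.asarray(targets, dtype=float).ravel()
    if o.shape != t.shape:
        raise ValueError("outputs and targets must have equal lengths")
    if o.std() == 0 or t.std() == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(np.corrcoef(o, t)[0, 1])


def paired_t_test(acc_a, acc_b) -> tuple[float, float]:
    """Classical paired t statistic and two-sided p value.

    Degenerate cases are handled explicitly: identical vectors give
    (t=0, p=1); a constant non-zero difference gives (t=+/-inf, p=0).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def one_way_anova(groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p value across accuracy groups.

    Convention for the fully degenerate case (every observation in every
    group identical): F = 0, p = 1 (no evidence of group differences).
    A zero within-group variance with distinct group means yields
    (inf, 0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.ndim != 1 or len(g) < 2:
            raise ValueError("each group must be a 1-D vector with n >= 2")
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    if within == 0:
        return float("inf"), 0.0
    with np.errstate(invalid="ignore"):
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
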