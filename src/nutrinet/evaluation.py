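"""Cross-validated fitness, confusion metrics, ROC/AUC and permutation tests.

Both wrapper methods score a candidate factor subset by the same fitness:
the data are split once into three folds; for each fold i a network is
trained on the other two folds (~67% of subjects) and tested on fold i
(~33%); the fold's summary is the average of its training and testing
accuracy, and the fitness F is the mean of the three fold summaries (a
percentage).  Algebraically F also equals (mean training accuracy + mean
testing accuracy) / 2.

ROC curves follow the fixed-grid procedure: the output neuron is
thresholded over [0, 1] in steps of 0.02 (51 thresholds), predicting
positive when output >= threshold, and the true-positive rate is plotted
against the false-positive rate; AUC is the trapezoidal area.

Significance uses a permutation test: the test-set class labels are
permuted S times with the model's outputs held fixed, the statistic is
recomputed each time, and p = (R + 1) / (S + 1) where R counts permuted
values strictly exceeding the observed one (counting ties into R is
available as a more conservative option).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .ann import NetworkConfig, TrainedNetwork, train

__all__ = [
    "CVPlan",
    "FoldResult",
    "MetricReport",
    "make_3cv",
    "cross_validate",
    "fitness",
    "confusion_metrics",
    "roc_curve",
    "auc",
    "permutation_test",
    "evaluate_model",
]

ROC_STEP = 0.02


@dataclass(frozen=True)
class CVPlan:
    """A k-fold partition of subject indices (k=3 for the study design)."""

    folds: tuple[np.ndarray, ...]
    seed: int
    stratified: bool

    @property
    def n_subjects(self) -> int:
        return sum(len(f) for f in self.folds)

    def train_indices(self, i: int) -> np.ndarray:
        others = [f for j, f in enumerate(self.folds) if j != i]
        return np.sort(np.concatenate(others))


def make_3cv(
    n_subjects: int,
    seed: int,
    stratify_labels: Sequence[int] | None = None,
    n_folds: int = 3,
) -> CVPlan:
    """Randomly partition subjects into three folds of near-equal size.

    With ``stratify_labels`` (the default entry point passes the class
    vector) each class is dealt round-robin across folds, keeping every
    fold's class ratio within one subject of the overall ratio while fold
    sizes still differ by at most one.
    """
    if n_subjects < n_folds:
        raise ValueError(f"need >= {n_folds} subjects, got {n_subjects}")
    rng = np.random.default_rng(seed)
    buckets: list[list[int]] = [[] for _ in range(n_folds)]
    if stratify_labels is None:
        order = rng.permutation(n_subjects)
        for k, idx in enumerate(order):
            buckets[k % n_folds].append(int(idx))
        stratified = False
    else:
        labels = np.asarray(stratify_labels)
        if labels.shape != (n_subjects,):
            raise ValueError("stratify_labels must have one entry per subject")
        ptr = 0  # global round-robin pointer keeps fold sizes within 1
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            members = members[rng.permutation(len(members))]
            for idx in members:
                buckets[ptr % n_folds].append(int(idx))
                ptr += 1
        stratified = True
    folds = tuple(np.sort(np.array(b, dtype=np.int64)) for b in buckets)
    return CVPlan(folds=folds, seed=seed, stratified=stratified)


@dataclass
class FoldResult:
    """Per-fold training/testing accuracies (%) and the trained networks."""

    train_acc: np.ndarray  # (k,) percent
    test_acc: np.ndarray  # (k,) percent
    networks: list[TrainedNetwork] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.train_acc = np.asarray(self.train_acc, dtype=float)
        self.test_acc = np.asarray(self.test_acc, dtype=float)
        if self.train_acc.shape != self.test_acc.shape:
            raise ValueError("train/test accuracy vectors differ in length")
        for a in (self.train_acc, self.test_acc):
            if np.any((a < 0) | (a > 100)):
                raise ValueError("accuracies must be in [0, 100] percent")

    @property
    def fold_means(self) -> np.ndarray:
        """Per-fold average of training and testing accuracy (%)."""
        return (self.train_acc + self.test_acc) / 2.0

    @property
    def mean_train(self) -> float:
        return float(self.train_acc.mean())

    @property
    def mean_test(self) -> float:
        return float(self.test_acc.mean())


def fitness(fold_result: FoldResult) -> float:
    """Mean over folds of each fold's average train/test accuracy (%)."""
    return float(fold_result.fold_means.mean())


def _accuracy_pct(pred: np.ndarray, y: np.ndarray) -> float:
    return 100.0 * float(np.mean(pred == y))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig,
    plan: CVPlan,
    base_seed: int,
    keep_networks: bool = True,
) -> FoldResult:
    """Train one network per fold and collect train/test accuracies.

    Each fold's network gets a seed derived from (base_seed, fold index)
    so a rerun with the same arguments is bit-identical.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    train_acc, test_acc, nets = [], [], []
    for i, test_idx in enumerate(plan.folds):
        tr_idx = plan.train_indices(i)
        cfg = NetworkConfig(
            **{**config.__dict__, "seed": derive_seed(base_seed, "fold", i)}
        )
        net = train(cfg, X[tr_idx], y[tr_idx])
        train_acc.append(_accuracy_pct(net.predict01(X[tr_idx]), y[tr_idx]))
        test_acc.append(_accuracy_pct(net.predict01(X[test_idx]), y[test_idx]))
        if keep_networks:
            nets.append(net)
    return FoldResult(
        train_acc=np.array(train_acc), test_acc=np.array(test_acc), networks=nets
    )


# ---------------------------------------------------------------------------
# confusion metrics and ROC


def confusion_metrics(
    predictions: Sequence[int], labels: Sequence[int]
) -> dict[str, float]:
    """Accuracy, sensitivity and specificity in percent (positive = C2 = 1).

    Sensitivity is the true-positive rate on overweight subjects,
    specificity the true-negative rate on normal subjects.  A rate whose
    denominator is empty is reported as NaN, never silently as zero.
    """
    pred = np.asarray(predictions).astype(np.int64)
    y = np.asarray(labels).astype(np.int64)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    pos, neg = tp + fn, tn + fp
    return {
        "accuracy": 100.0 * (tp + tn) / (pos + neg),
        "sensitivity": 100.0 * tp / pos if pos else float("nan"),
        "specificity": 100.0 * tn / neg if neg else float("nan"),
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
    }


def roc_curve(
    outputs: Sequence[float], labels: Sequence[int], step: float = ROC_STEP
) -> np.ndarray:
    """(FPR, TPR) points from thresholding the output on a fixed grid.

    Thresholds run over [0, 1] in steps of ``step`` (0.02 -> 51 values);
    a subject is predicted positive when output >= threshold.  Points are
    returned in threshold order: threshold 0 gives (1, 1), a threshold
    above every output gives (0, 0).
    """
    o = np.asarray(outputs, dtype=float)
    y = np.asarray(labels).astype(np.int64)
    if np.any((o < 0) | (o > 1)):
        raise ValueError("outputs must lie in [0, 1]")
    pos = int(np.sum(y == 1))
    neg = int(np.sum(y == 0))
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present to form a ROC curve")
    thresholds = np.arange(0.0, 1.0 + step / 2, step)
    pts = np.empty((thresholds.size, 2))
    for k, t in enumerate(thresholds):
        pred = o >= t
        pts[k, 0] = np.sum(pred & (y == 0)) / neg  # FPR
        pts[k, 1] = np.sum(pred & (y == 1)) / pos  # TPR
    return pts


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under (FPR, TPR) points, anchored at (0,0), (1,1)."""
    pts = np.asarray(points, dtype=float)
    pts = np.vstack([pts, [0.0, 0.0], [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


# ---------------------------------------------------------------------------
# permutation significance


def permutation_test(
    observed_stat: float,
    stat_fn: Callable[[np.ndarray, np.ndarray], float],
    outputs: np.ndarray,
    labels: np.ndarray,
    S: int = 1000,
    rng: np.random.Generator | int | None = None,
    ties: Literal["strict", "count"] = "strict",
) -> float:
    """Unbiased permutation p-value p = (R + 1) / (S + 1).

    The class labels are permuted S times with the model outputs (or hard
    predictions) fixed; R counts permuted statistic values strictly
    exceeding the observed one.  ``ties="count"`` also counts exact ties
    into R, which is more conservative.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    outputs = np.asarray(outputs)
    labels = np.asarray(labels)
    R = 0
    for _ in range(S):
        perm = rng.permutation(labels)
        val = stat_fn(outputs, perm)
        if val > observed_stat or (ties == "count" and val == observed_stat):
            R += 1
    return (R + 1) / (S + 1)


# ---------------------------------------------------------------------------
# full model report


@dataclass
class MetricReport:
    """Fold-averaged accuracy/sensitivity/specificity/AUC for train and test."""

    train: dict[str, float]
    test: dict[str, float]
    per_fold: list[dict[str, dict[str, float]]]
    roc_points_test: list[np.ndarray]
    p_values: dict[str, float] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "train": self.train,
            "test": self.test,
            "per_fold": self.per_fold,
            "p_values": self.p_values,
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def roc_to_csv(self, path: str | Path) -> None:
        rows = []
        for i, pts in enumerate(self.roc_points_test):
            for fpr, tpr in pts:
                rows.append({"fold": i + 1, "fpr": fpr, "tpr": tpr})
        pd.DataFrame(rows).to_csv(path, index=False)


def _fold_metrics(net: TrainedNetwork, X, y) -> tuple[dict[str, float], np.ndarray]:
    out = np.atleast_1d(net.forward(X))
    m = confusion_metrics((out >= 0.5).astype(int), y)
    pts = roc_curve(out, y)
    m["auc"] = auc(pts)
    return m, pts


def evaluate_model(
    fold_result: FoldResult,
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    permutations: int = 0,
    seed: int = 0,
) -> MetricReport:
    """Fold-averaged metric report for trained 3-CV networks.

    With ``permutations`` = S > 0, each test-set metric additionally gets
    a permutation p-value per fold; per-fold p-values are averaged for the
    reported mean p.
    """
    if not fold_result.networks:
        raise ValueError("fold_result must retain its trained networks")
    keys = ("accuracy", "sensitivity", "specificity", "auc")
    per_fold, rocs = [], []
    p_acc: dict[str, list[float]] = {k: [] for k in keys}
    for i, net in enumerate(fold_result.networks):
        tr_idx = plan.train_indices(i)
        te_idx = plan.folds[i]
        m_tr, _ = _fold_metrics(net, X[tr_idx], y[tr_idx])
        m_te, pts = _fold_metrics(net, X[te_idx], y[te_idx])
        per_fold.append({"train": m_tr, "test": m_te})
        rocs.append(pts)
        if permutations > 0:
            out = np.atleast_1d(net.forward(X[te_idx]))
            rng = np.random.default_rng(derive_seed(seed, "perm", i))
            stat_fns = {
                "accuracy": lambda o, yy: confusion_metrics(
                    (o >= 0.5).astype(int), yy
                )["accuracy"],
                "sensitivity": lambda o, yy: confusion_metrics(
                    (o >= 0.5).astype(int), yy
                )["sensitivity"],
                "specificity": lambda o, yy: confusion_metrics(
                    (o >= 0.5).astype(int), yy
                )["specificity"],
                "auc": lambda o, yy: auc(roc_curve(o, yy)),
            }
            for k in keys:
                p_acc[k].append(
                    permutation_test(
                        m_te[k], stat_fns[k], out, y[te_idx], S=permutations, rng=rng
                    )
                )
    train = {k: float(np.mean([f["train"][k] for f in per_fold])) for k in keys}
    test = {k: float(np.mean([f["test"][k] for f in per_fold])) for k in keys}
    p_values = (
        {k: float(np.mean(v)) for k, v in p_acc.items()} if permutations > 0 else None
    )
    return MetricReport(
        train=train, test=test, per_fold=per_fold, roc_points_test=rocs,
        p_values=p_values,
    )
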