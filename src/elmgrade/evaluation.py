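"""Repeated stratified 10-fold cross-validation of pMCI/sMCI classification.

Each repetition permutes the MCI subjects with a run-specific random stream,
splits them into k near-equal stratified folds, trains a kernel ELM
classifier (gamma = 10 * number of score columns, C = 1) on k-1 folds and
predicts the held-out fold.  Predictions and grading scores are pooled over
the k folds of a run to give one set of metrics per run; the summary is the
mean and standard deviation over all runs.

Metrics (positive class = pMCI):
  ACC  = (TP+TN)/N
  SEN  = TP/(TP+FN)
  SPE  = TN/(TN+FP)
  BACC = (SEN+SPE)/2       (the unweighted balanced accuracy)
  AUC  = Mann-Whitney probability P(score_pos > score_neg) + P(tie)/2,
         computed on the pooled out-of-fold grading scores of the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from elmgrade.cohort_io import CohortTable
from elmgrade.grading_pipeline import (
    GradingScoreMatrix,
    ModalitySpec,
    build_modalities,
)
from elmgrade.kernel_elm import DEFAULT_C, default_gamma, elm_grade, elm_train

POSITIVE_CLASS = "pMCI"
NEGATIVE_CLASS = "sMCI"


@dataclass
class RunMetrics:
    """Metrics of one cross-validation repetition (fractions in [0, 1])."""

    acc: float
    sen: float
    spe: float
    bacc: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "bacc": self.bacc,
            "auc": self.auc,
        }


METRIC_NAMES = ("acc", "sen", "spe", "bacc", "auc")


@dataclass
class CvSummary:
    """Per-run metrics plus mean +/- SD (sample SD, divisor n-1) over runs."""

    per_run: list[RunMetrics]
    runs: int
    k: int
    seed: int

    def _values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.per_run])

    def mean(self, metric: str) -> float:
        return float(self._values(metric).mean())

    def sd(self, metric: str) -> float:
        v = self._values(metric)
        return float(v.std(ddof=1)) if v.size > 1 else 0.0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(METRIC_NAMES),
                "mean": [self.mean(m) for m in METRIC_NAMES],
                "sd": [self.sd(m) for m in METRIC_NAMES],
            }
        )

    def per_run_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.per_run])

    def __str__(self) -> str:  # percent display, 1 decimal; internals full precision
        parts = [
            f"{m.upper()} {100 * self.mean(m):.1f} +/- {100 * self.sd(m):.1f}%"
            for m in METRIC_NAMES
        ]
        return f"CV ({self.runs} x {self.k}-fold): " + ", ".join(parts)


def balanced_accuracy(sen: float, spe: float) -> float:
    """BACC = (SEN + SPE) / 2, the unweighted mean of the class recalls."""
    return (sen + spe) / 2.0


def confusion_metrics(
    pred: np.ndarray, truth: np.ndarray, positive_class: str = POSITIVE_CLASS
) -> tuple[float, float, float, float]:
    """(ACC, SEN, SPE, BACC) from hard predictions."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    pos = truth == positive_class
    if pos.all() or not pos.any():
        raise ValueError("truth must contain both classes")
    hit = pred == truth
    acc = float(hit.mean())
    sen = float(hit[pos].mean())
    spe = float(hit[~pos].mean())
    return acc, sen, spe, balanced_accuracy(sen, spe)


def roc_auc(
    score: np.ndarray, truth: np.ndarray, positive_class: str = POSITIVE_CLASS
) -> float:
    """Rank-based (Mann-Whitney) AUC of a continuous score; ties count 1/2."""
    score = np.asarray(score, dtype=float)
    truth = np.asarray(truth)
    pos = truth == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both classes")
    if np.all(score == score[0]):
        warnings.warn("constant scores: AUC is 0.5", RuntimeWarning, stacklevel=2)
        return 0.5
    ranks = rankdata(score)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def fold_assignments(
    labels: np.ndarray, k: int, runs: int, seed: int, max_redraws: int = 100
) -> np.ndarray:
    """Stratified fold ids, shape (runs, N), entries in 0..k-1.

    Run r consumes the substream ``SeedSequence(seed, spawn_key=(r,))``, so
    assignments depend only on (labels, k, runs, seed) — any consumer called
    with the same arguments sees identical folds.  Within a run the subjects
    of each class are permuted and dealt cyclically to the folds, preserving
    class proportions.  A permutation whose training sets would miss a class
    is redrawn (this cannot be fixed by redrawing when a class has a single
    member, which the N >= 2k precondition effectively rules out).
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} subjects, got {n}")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    out = np.empty((runs, n), dtype=int)
    for r in range(runs):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        for attempt in range(max_redraws):
            folds = np.empty(n, dtype=int)
            counter = 0
            for cls in classes:
                idx = np.flatnonzero(labels == cls)
                idx = idx[rng.permutation(idx.size)]
                for i in idx:
                    folds[i] = counter % k
                    counter += 1
            ok = all(
                np.unique(labels[folds != f]).size == classes.size for f in range(k)
            )
            if ok:
                break
            warnings.warn(
                f"run {r}: single-class training fold, redrawing permutation",
                RuntimeWarning,
                stacklevel=2,
            )
        out[r] = folds
    return out


def _as_matrix(scores) -> tuple[np.ndarray, int]:
    if isinstance(scores, GradingScoreMatrix):
        return scores.values, scores.k
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] == 1 and X.size > 1:
        X = X.T
    return X, X.shape[1]


def repeated_kfold(
    scores,
    labels: np.ndarray,
    k: int = 10,
    runs: int = 100,
    seed: int = 0,
    C: float = DEFAULT_C,
    gamma: float | None = None,
    positive_class: str = POSITIVE_CLASS,
) -> CvSummary:
    """Repeated stratified k-fold CV of the kernel-ELM classifier.

    ``scores`` is a :class:`GradingScoreMatrix` or a plain N x K array
    aligned with ``labels``.  The per-fold classifier uses gamma = 10 * K
    unless overridden.  Deterministic given ``seed``; a
    :class:`GradingScoreMatrix` is first put in subject-id order so the
    result does not depend on input row order.
    """
    X, n_cols = _as_matrix(scores)
    labels = np.asarray(labels).astype(str)
    if X.shape[0] != labels.size:
        raise ValueError("scores and labels misaligned")
    if isinstance(scores, GradingScoreMatrix):
        order = np.argsort(scores.subject_ids)
        X = X[order]
        labels = labels[order]
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    negative_class = next(c for c in classes if c != positive_class)
    class_order = (positive_class, negative_class)
    if gamma is None:
        gamma = default_gamma(n_cols)

    assignments = fold_assignments(labels, k, runs, seed)
    per_run: list[RunMetrics] = []
    for r in range(runs):
        folds = assignments[r]
        pred = np.empty(labels.size, dtype=object)
        grade = np.empty(labels.size, dtype=float)
        for f in range(k):
            test = folds == f
            model = elm_train(
                X[~test], labels[~test], C=C, gamma=gamma, class_order=class_order
            )
            g = np.asarray(elm_grade(model, X[test]))
            grade[test] = g
            pred[test] = np.where(g > 0, class_order[0], class_order[1])
        acc, sen, spe, bacc = confusion_metrics(
            pred.astype(str), labels, positive_class
        )
        auc = roc_auc(grade, labels, positive_class)
        per_run.append(RunMetrics(acc=acc, sen=sen, spe=spe, bacc=bacc, auc=auc))
    return CvSummary(per_run=per_run, runs=runs, k=k, seed=seed)


def out_of_fold_scores(
    scores,
    labels: np.ndarray,
    k: int = 10,
    runs: int = 1,
    run: int = 0,
    seed: int = 0,
    C: float = DEFAULT_C,
    gamma: float | None = None,
    positive_class: str = POSITIVE_CLASS,
) -> np.ndarray:
    """Pooled out-of-fold grading scores of one CV repetition.

    Uses the same fold assignments as :func:`repeated_kfold` at equal
    arguments; mainly for exporting ROC curves.
    """
    X, n_cols = _as_matrix(scores)
    labels = np.asarray(labels).astype(str)
    classes = sorted(np.unique(labels).tolist())
    negative_class = next(c for c in classes if c != positive_class)
    if gamma is None:
        gamma = default_gamma(n_cols)
    folds = fold_assignments(labels, k, max(runs, run + 1), seed)[run]
    grade = np.empty(labels.size, dtype=float)
    for f in range(k):
        test = folds == f
        model = elm_train(
            X[~test],
            labels[~test],
            C=C,
            gamma=gamma,
            class_order=(positive_class, negative_class),
        )
        grade[test] = np.asarray(elm_grade(model, X[test]))
    return grade


def roc_points(
    score: np.ndarray, truth: np.ndarray, positive_class: str = POSITIVE_CLASS
) -> pd.DataFrame:
    """ROC curve (fpr, tpr, threshold) of a continuous score."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(
        np.asarray(truth) == positive_class, np.asarray(score, dtype=float)
    )
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def direct_concat_baseline(
    cohort: CohortTable,
    specs: list[ModalitySpec] | None = None,
    labels: np.ndarray | None = None,
    k: int = 10,
    runs: int = 100,
    seed: int = 0,
    C: float = DEFAULT_C,
    **build_kwargs,
) -> CvSummary:
    """Direct-concatenation comparison: skip grading entirely.

    The normalized (and, where configured, L1-selected) modality blocks of
    the MCI subjects are concatenated into one wide matrix and fed to the
    same CV harness with gamma = 10 * total column count.  With identical
    ``labels``/``k``/``runs``/``seed`` the fold assignments match the
    grading pipeline's exactly, so the comparison isolates the effect of
    per-modality grading.
    """
    if labels is None:
        raise ValueError("labels are required")
    modalities = build_modalities(cohort, specs, **build_kwargs)
    wide = np.hstack([md.test_block.values for md in modalities])
    return repeated_kfold(wide, labels, k=k, runs=runs, seed=seed, C=C)
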