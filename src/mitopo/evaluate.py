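"""Classifier evaluation: accuracy, Cohen's kappa, repeated stratified CV,
and the Welch t-test used to compare electrode-dropping strategies.

Accuracy is the fraction of correctly classified trials (trace of the
confusion matrix over its total).  Kappa corrects for chance agreement,
kappa = (a_c - p_e) / (1 - p_e), with p_e = 1/2 for two classes and 1/3 for
three.  Cross-validation is stratified 10-fold, repeated 10 times with
reshuffled partitions by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import RepeatedStratifiedKFold

from .model import ModelConfig, TrainedModel, build_model, predict_proba
from .model import train as train_model

__all__ = ["ConfusionCounts", "CVResult", "confusion", "accuracy", "kappa",
           "stratified_cv", "welch_ttest"]


@dataclass
class ConfusionCounts:
    """A K x K confusion matrix; rows = true class, columns = predicted."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(m < 0):
            raise ValueError("confusion counts must be nonnegative")
        self.matrix = m

    @classmethod
    def from_binary(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionCounts":
        # convention: class 1 = positive; rows true, cols predicted
        return cls(np.array([[tn, fp], [fn, tp]]))

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion(y_true, y_pred, n_classes: int | None = None) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    k = n_classes or int(max(yt.max(), yp.max())) + 1
    m = np.zeros((k, k), dtype=int)
    np.add.at(m, (yt, yp), 1)
    return ConfusionCounts(m)


def accuracy(counts: ConfusionCounts) -> float:
    """Fraction correct: (T_P + T_N) / total, i.e. trace / total in general."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(counts.matrix) / counts.total)


def kappa(a_c: float, p_e: float = 0.5) -> float:
    """Chance-corrected agreement; may be negative below chance level."""
    if p_e >= 1.0:
        raise ValueError("p_e must be < 1")
    return (a_c - p_e) / (1.0 - p_e)


@dataclass
class CVResult:
    fold_scores: np.ndarray       # repeats x folds
    config: ModelConfig
    seed: int
    models: list | None = None    # per-fold TrainedModel when requested

    @property
    def mean(self) -> float:
        return float(self.fold_scores.mean())

    @property
    def std(self) -> float:
        return float(self.fold_scores.std(ddof=1))

    @property
    def kappa(self) -> float:
        return kappa(self.mean, p_e=1.0 / self.config.n_classes)

    @property
    def table(self) -> pd.DataFrame:
        rows = [{"repeat": r, "fold": f, "accuracy": s}
                for (r, f), s in np.ndenumerate(self.fold_scores)]
        return pd.DataFrame(rows)


def stratified_cv(images, labels, cfg: ModelConfig, folds: int = 10,
                  repeats: int = 10, seed: int = 0,
                  input_mask: np.ndarray | None = None,
                  return_models: bool = False) -> CVResult:
    """Repeated stratified k-fold CV of the CNN on per-band image stacks.

    Class proportions are preserved per fold (within one trial); every trial
    is tested exactly once per repeat; partitions and model initialization
    are fully determined by ``seed``.
    """
    x = np.asarray(images, dtype=float)
    y_raw = np.asarray(labels)
    classes, y = np.unique(y_raw, return_inverse=True)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs >= {folds} trials for {folds}-fold CV "
            f"(got {dict(zip(classes, counts))})")
    cfg = replace(cfg, n_classes=len(classes))
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                       random_state=seed % (2 ** 31))
    scores = np.empty((repeats, folds))
    models = [] if return_models else None
    for split_i, (tr, te) in enumerate(splitter.split(x, y)):
        fold_cfg = replace(cfg, seed=(cfg.seed + 1000 * split_i) % (2 ** 31))
        model = build_model(fold_cfg, input_mask=input_mask)
        train_model(model, x[tr], y[tr], fold_cfg)
        pred = predict_proba(model, x[te]).argmax(axis=1)
        scores[split_i // folds, split_i % folds] = accuracy(
            confusion(y[te], pred, n_classes=len(classes)))
        if return_models:
            models.append(model)
    return CVResult(fold_scores=scores, config=cfg, seed=seed, models=models)


def welch_ttest(scores_a, scores_b, paired: bool = False) -> float:
    """Two-sided p-value for equal mean fold scores.

    Welch's unequal-variance two-sample test by default (a paired t-test is
    available behind the flag).  Degenerate rule: if both samples have zero
    variance the p-value is 1 when the means agree and 0 otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two scores per sample")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    if paired:
        return float(stats.ttest_rel(a, b).pvalue)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
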