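"""Cross-validation, confusion matrices, ROC/AUC, and scorer comparison.

Fold hygiene matters here: the positional probability matrices are
re-estimated inside every training split, never from held-out windows, so
pooled out-of-fold scores are honest.  ROC curves are computed from those
pooled scores; per-fold AUCs are reported alongside and their mean is the
"average AUC".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .io_genomics import AirlinerError, SequenceWindow
from .model import AirlinerModel, AirlinerResults, MultiplicativeScorer

__all__ = [
    "ConfusionMatrixPct",
    "RocResult",
    "CrossValidationResult",
    "ComparisonResult",
    "stratified_folds",
    "kfold_cross_validate",
    "confusion_matrix_pct",
    "roc_auc",
    "compare_scorers",
]


@dataclass(frozen=True)
class ConfusionMatrixPct:
    """Row-normalized confusion matrix, presented as percentages.

    Rows are the actual class (edited, random); columns the predicted class
    (edited, unedited).  ``counts`` holds the raw integer cross-tabulation.
    """

    counts: np.ndarray  # shape (2, 2)
    row_labels: tuple[str, str] = ("edited", "random")
    col_labels: tuple[str, str] = ("edited", "unedited")

    @property
    def percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return np.where(totals > 0, pct, 0.0)

    def __str__(self) -> str:
        pct = self.percentages
        lines = [f"{'':>10s} {self.col_labels[0]:>10s} {self.col_labels[1]:>10s}"]
        for r, lab in enumerate(self.row_labels):
            lines.append(f"{lab:>10s} {pct[r, 0]:>10.2f} {pct[r, 1]:>10.2f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class RocResult:
    """ROC curve (FPR/TPR over grouped score thresholds) and trapezoid AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion_matrix_pct(
    calls: Sequence[str], truth: Sequence[str]
) -> ConfusionMatrixPct:
    """Cross-tabulate predicted vs actual labels, row-normalized to percent.

    ``truth`` uses {'edited', 'random'}; ``calls`` uses {'edited',
    'unedited'}.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must have equal length")
    if len(calls) == 0:
        raise AirlinerError("cannot tabulate an empty evaluation")
    counts = np.zeros((2, 2), dtype=int)
    row = {"edited": 0, "random": 1}
    col = {"edited": 0, "unedited": 1}
    for c, t in zip(calls, truth):
        counts[row[t], col[c]] += 1
    return ConfusionMatrixPct(counts=counts)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve over all distinct score thresholds and its trapezoid AUC.

    Tied scores are grouped into a single threshold step, so the curve is
    deterministic regardless of input ordering.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise AirlinerError("AUC is undefined with a single class")
    fpr, tpr, thr = _roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr))
    )


def stratified_folds(
    labels: Sequence[int], k: int, seed: int
) -> list[np.ndarray]:
    """Seeded stratified fold assignment: list of k test-index arrays.

    Within each class, indices are shuffled with the seed and dealt
    round-robin across folds, giving near-equal fold sizes and class
    balance.  Every observation appears in exactly one test fold.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(labels):
        raise ValueError("k cannot exceed the number of observations")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0  # carried across classes so k = n yields singleton folds
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[cursor % k].append(int(i))
            cursor += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass
class CrossValidationResult:
    """Per-fold metrics plus pooled out-of-fold scores."""

    k: int
    seed: int
    fold_indices: list[np.ndarray]
    fold_errors: list[float]
    fold_aucs: list[float]
    pooled_scores: np.ndarray  # out-of-fold probability per observation
    labels: np.ndarray
    threshold: float = 0.5

    @property
    def mean_error(self) -> float:
        """Mean misclassification rate over folds at the decision threshold."""
        return float(np.mean(self.fold_errors))

    @property
    def accuracy(self) -> float:
        calls = self.pooled_scores > self.threshold
        return float(np.mean(calls == (self.labels == 1)))

    @property
    def pooled_roc(self) -> RocResult:
        return roc_auc(self.pooled_scores, self.labels)

    @property
    def mean_fold_auc(self) -> float:
        finite = [a for a in self.fold_aucs if np.isfinite(a)]
        return float(np.mean(finite)) if finite else float("nan")

    def confusion(self) -> ConfusionMatrixPct:
        calls = [
            "edited" if s > self.threshold else "unedited" for s in self.pooled_scores
        ]
        truth = ["edited" if y == 1 else "random" for y in self.labels]
        return confusion_matrix_pct(calls, truth)


def kfold_cross_validate(
    windows_pos: Sequence[SequenceWindow],
    windows_neg: Sequence[SequenceWindow],
    k: int = 10,
    seed: int = 42,
    ridge: float = 1e-3,
    pseudocount: float = 1.0,
    threshold: float = 0.5,
    leak_all_data: bool = False,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of the editing model.

    For each fold, both probability matrices and the logistic coefficients
    are estimated from the remaining k-1 folds only and applied to the
    held-out fold.  ``leak_all_data`` reproduces the naive variant that
    builds the matrices from the full dataset (for comparison only).

    Returns per-fold misclassification errors (at ``threshold``), per-fold
    AUCs (NaN when a test fold holds one class), and the pooled
    out-of-fold score table.
    """
    windows = list(windows_pos) + list(windows_neg)
    labels = np.concatenate(
        [np.ones(len(windows_pos), dtype=int), np.zeros(len(windows_neg), dtype=int)]
    )
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise AirlinerError("both classes are required for cross-validation")
    folds = stratified_folds(labels, k, seed)
    pooled = np.full(len(windows), np.nan)
    fold_errors: list[float] = []
    fold_aucs: list[float] = []
    leaky_ppms = None
    if leak_all_data:
        from .profiles import build_profile

        leaky_ppms = (
            build_profile(list(windows_pos), pseudocount),
            build_profile(list(windows_neg), pseudocount),
        )
    for test_idx in folds:
        test_mask = np.zeros(len(windows), dtype=bool)
        test_mask[test_idx] = True
        train_pos = [w for w, y, m in zip(windows, labels, test_mask) if y == 1 and not m]
        train_neg = [w for w, y, m in zip(windows, labels, test_mask) if y == 0 and not m]
        if not train_pos or not train_neg:
            raise AirlinerError(
                "a class is absent from a training split; reduce k or add data"
            )
        results = _fit_fold(
            train_pos, train_neg, ridge, pseudocount, leaky_ppms
        )
        scores = results.predict_probabilities([windows[i] for i in test_idx])
        pooled[test_idx] = scores
        y_test = labels[test_idx]
        calls = scores > threshold
        fold_errors.append(float(np.mean(calls != (y_test == 1))))
        if len(np.unique(y_test)) == 2:
            fold_aucs.append(roc_auc(scores, y_test).auc)
        else:
            fold_aucs.append(float("nan"))
    return CrossValidationResult(
        k=k,
        seed=seed,
        fold_indices=folds,
        fold_errors=fold_errors,
        fold_aucs=fold_aucs,
        pooled_scores=pooled,
        labels=labels,
        threshold=threshold,
    )


def _fit_fold(train_pos, train_neg, ridge, pseudocount, leaky_ppms):
    """Fit one CV fold; ``leaky_ppms`` substitutes all-data matrices."""
    if leaky_ppms is None:
        return AirlinerModel(
            train_pos, train_neg, ridge=ridge, pseudocount=pseudocount
        ).fit()
    from .model import AirlinerResults, _signed_design, fit_penalized_logistic
    from .profiles import featurize_many

    ppm_pos, ppm_neg = leaky_ppms
    windows = list(train_pos) + list(train_neg)
    y = np.concatenate([np.ones(len(train_pos)), np.zeros(len(train_neg))])
    X = _signed_design(featurize_many(windows, ppm_pos, ppm_neg), ppm_pos.radius)
    params, info = fit_penalized_logistic(X, y, ridge=ridge)
    width = 2 * ppm_pos.radius + 1
    return AirlinerResults(
        beta0=float(params[0]),
        beta=params[1 : width + 1],
        beta_prime=params[width + 1 :],
        radius=ppm_pos.radius,
        ridge=ridge,
        ppm_edited=ppm_pos,
        ppm_unedited=ppm_neg,
        fit_info={k: v for k, v in info.items() if k != "cov"},
    )


@dataclass
class ComparisonResult:
    """Paired evaluation of the logistic model against a baseline scorer."""

    primary_roc: RocResult
    secondary_roc: RocResult
    primary_confusion: ConfusionMatrixPct
    secondary_confusion: ConfusionMatrixPct
    primary_scores: np.ndarray
    secondary_scores: np.ndarray
    labels: np.ndarray


def compare_scorers(
    windows: Sequence[SequenceWindow],
    labels: Sequence[int],
    primary: AirlinerResults,
    secondary: MultiplicativeScorer | Sequence[MultiplicativeScorer],
    selection: Literal["max_for_pos_min_for_neg", "single"] = "single",
    primary_threshold: float = 0.5,
) -> ComparisonResult:
    """Score every window with both methods and tabulate ROC + confusions.

    With ``selection='max_for_pos_min_for_neg'`` the baseline must supply
    at least two coefficient tables (e.g. ADAR1-like and ADAR2-like); each
    truly edited window takes the maximum score over tables and each random
    window the minimum — a fairness protocol for datasets that do not
    record which deaminase acts on each site.  The logistic model is scored
    normally and thresholded at ``primary_threshold``; the baseline at its
    own percent cutoff.
    """
    tables = [secondary] if isinstance(secondary, MultiplicativeScorer) else list(secondary)
    if selection == "max_for_pos_min_for_neg" and len(tables) < 2:
        raise AirlinerError(
            "max/min selection requires at least two baseline coefficient tables"
        )
    labels = np.asarray(labels, dtype=int)
    primary_scores = primary.predict_probabilities(windows)
    secondary_scores = np.empty(len(windows))
    for i, (w, y) in enumerate(zip(windows, labels)):
        per_table = [t.score(w) for t in tables]
        if selection == "max_for_pos_min_for_neg":
            secondary_scores[i] = max(per_table) if y == 1 else min(per_table)
        else:
            secondary_scores[i] = per_table[0]
    cutoff = tables[0].threshold_percent
    truth = ["edited" if y == 1 else "random" for y in labels]
    primary_calls = [
        "edited" if s > primary_threshold else "unedited" for s in primary_scores
    ]
    secondary_calls = [
        "edited" if s > cutoff else "unedited" for s in secondary_scores
    ]
    return ComparisonResult(
        primary_roc=roc_auc(primary_scores, labels),
        secondary_roc=roc_auc(secondary_scores, labels),
        primary_confusion=confusion_matrix_pct(primary_calls, truth),
        secondary_confusion=confusion_matrix_pct(secondary_calls, truth),
        primary_scores=primary_scores,
        secondary_scores=secondary_scores,
        labels=labels,
    )
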