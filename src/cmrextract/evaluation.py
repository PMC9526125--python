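"""Token-level evaluation: per-label P/R/F1, macro-F1, bootstrap CIs, ROC,
and learning-curve experiments.

The headline metric is the macro-averaged F1 over measurement labels: the
unweighted mean of per-label token-level F1 scores, so a rare measurement
counts as much as a frequent one.  The null label never enters the macro
average; measurement labels absent from both gold and predictions are
excluded by default (they carry no information) — pass
``include_missing=True`` to count them as zero instead.

Bootstrap confidence intervals resample whole reports with replacement,
respecting within-report correlation of tokens, and take percentile bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc, precision_recall_fscore_support, roc_curve

__all__ = ["EvalResult", "evaluate", "bootstrap_ci", "roc_per_label", "learning_curve"]


@dataclass
class EvalResult:
    """Per-label precision/recall/F1 and their macro average."""

    per_label: dict[int, dict[str, float]]
    macro_f1: float
    support: dict[int, int] = field(default_factory=dict)
    ci: tuple[float, float] | None = None


def evaluate(
    predicted: Sequence[int],
    gold: Sequence[int],
    n_labels: int = 22,
    include_missing: bool = False,
) -> EvalResult:
    """Token-level per-label P/R/F1 and macro-F1 over measurement labels.

    ``predicted`` and ``gold`` are aligned label-id sequences over the same
    tokens (0 = null).  Labels with zero gold and zero predicted tokens are
    excluded from the macro average unless ``include_missing``.
    """
    predicted = np.asarray(predicted, dtype=int)
    gold = np.asarray(gold, dtype=int)
    if predicted.shape != gold.shape:
        raise ValueError(
            f"prediction/gold length mismatch: {predicted.shape} vs {gold.shape}"
        )
    labels = np.arange(1, n_labels)  # measurement labels; null excluded
    prec, rec, f1, support = precision_recall_fscore_support(
        gold, predicted, labels=labels, zero_division=0.0, average=None
    )
    n_pred = {lab: int(np.sum(predicted == lab)) for lab in labels}
    per_label: dict[int, dict[str, float]] = {}
    included = []
    for i, lab in enumerate(labels):
        present = support[i] > 0 or n_pred[lab] > 0
        if present or include_missing:
            per_label[int(lab)] = {
                "precision": float(prec[i]),
                "recall": float(rec[i]),
                "f1": float(f1[i]),
            }
            included.append(float(f1[i]))
    macro = float(np.mean(included)) if included else 0.0
    return EvalResult(
        per_label=per_label,
        macro_f1=macro,
        support={int(lab): int(support[i]) for i, lab in enumerate(labels)},
    )


def bootstrap_ci(
    predicted_by_report: dict[str, Sequence[int]],
    gold_by_report: dict[str, Sequence[int]],
    n_labels: int = 22,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for macro-F1, resampling whole reports.

    Deterministic for a fixed seed.  With a single report the interval is
    degenerate (lo == hi).
    """
    ids = sorted(gold_by_report)
    if set(predicted_by_report) != set(gold_by_report):
        raise ValueError("prediction and gold report ids differ")
    if len(ids) == 1:
        import warnings

        warnings.warn("bootstrap over a single report yields a degenerate CI")
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    preds = {r: np.asarray(predicted_by_report[r], dtype=int) for r in ids}
    golds = {r: np.asarray(gold_by_report[r], dtype=int) for r in ids}
    for b in range(B):
        sample = rng.choice(len(ids), size=len(ids), replace=True)
        p = np.concatenate([preds[ids[i]] for i in sample])
        g = np.concatenate([golds[ids[i]] for i in sample])
        stats[b] = evaluate(p, g, n_labels=n_labels).macro_f1
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def roc_per_label(
    scores: np.ndarray,
    gold: Sequence[int],
    n_labels: int = 22,
) -> dict[int, dict]:
    """One-vs-rest ROC curve and AUC per measurement label.

    ``scores`` is a (n_tokens, n_labels) array of normalized token scores.
    Labels without gold positives get ``auc = None`` (undefined).
    """
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(gold, dtype=int)
    if scores.shape[0] != gold.shape[0]:
        raise ValueError("scores and gold must be aligned 1:1")
    out: dict[int, dict] = {}
    for lab in range(1, n_labels):
        y = (gold == lab).astype(int)
        if y.sum() == 0:
            out[lab] = {"fpr": None, "tpr": None, "auc": None}
            continue
        fpr, tpr, _ = roc_curve(y, scores[:, lab])
        out[lab] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return out


def learning_curve(
    train_units: Sequence,
    sizes: Sequence[int],
    fit_and_score: Callable[[list], float],
    seed: int = 0,
) -> dict[int, float]:
    """Macro-F1 as a function of the number of annotated training reports.

    ``train_units`` is the pool of training reports (any per-report unit the
    caller's closure understands); ``fit_and_score(subset) -> macro_f1``
    trains one model on the subset and evaluates it on a fixed test set.
    Subsets are nested (smaller contained in larger), drawn once from the
    seeded shuffle, so curve points differ only by training-set size.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in sizes):
        raise ValueError("training sizes must be >= 1")
    if sizes[-1] > len(train_units):
        raise ValueError(
            f"size {sizes[-1]} exceeds the {len(train_units)}-report training pool"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_units))
    curve: dict[int, float] = {}
    for s in sizes:
        subset = [train_units[i] for i in order[:s]]
        curve[s] = float(fit_and_score(subset))
    return curve
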