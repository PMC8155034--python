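"""CAFA-style evaluation: protein-centric Fmax, term-centric AUPR,
precision–recall curves, and bootstrap summaries.

Fmax follows the CAFA protein-centric convention: at each decision
threshold t, precision is averaged over the proteins with at least one
score >= t, recall over all proteins with at least one true term, and
F(t) is their harmonic mean; Fmax is the maximum over the threshold grid
(0.01 steps; t = 0, where everything is predicted, is excluded from the
max).  Term-centric AUPR is the non-interpolated step-wise area (average
precision), with tied scores collapsed into a single step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 1.01, 0.01), 2)


@dataclass
class EvaluationResult:
    fmax: float
    fmax_threshold: float
    pr_curve: pd.DataFrame
    aupr_per_term: dict = field(default_factory=dict)
    macro_aupr: float = float("nan")
    bootstrap: dict = field(default_factory=dict)


def fmax(scores: np.ndarray, labels: np.ndarray,
         thresholds: np.ndarray | None = None,
         include_zero_threshold: bool = False) -> tuple[float, float]:
    """Protein-centric maximum F-score over a threshold grid.

    Returns (Fmax, the threshold achieving it).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels shape mismatch")
    if labels.sum() == 0:
        raise ValueError("no positive labels in the evaluation set")
    grid = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds)
    curve = precision_recall_curve(scores, labels, grid)
    sel = curve if include_zero_threshold else curve[curve["threshold"] > 0]
    f = sel["f1"].to_numpy()
    best = int(np.argmax(f))
    return float(f[best]), float(sel["threshold"].to_numpy()[best])


def precision_recall_curve(scores: np.ndarray, labels: np.ndarray,
                           thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """CAFA protein-centric precision/recall at each threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    grid = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds)
    has_true = labels.sum(axis=1) > 0
    rows = []
    for t in grid:
        pred = scores >= t
        tp = (pred & (labels == 1)).sum(axis=1)
        npred = pred.sum(axis=1)
        covered = npred > 0
        pr = float((tp[covered] / npred[covered]).mean()) if covered.any() else 0.0
        rc = float((tp[has_true] / labels[has_true].sum(axis=1)).mean()) \
            if has_true.any() else 0.0
        f1 = 2 * pr * rc / (pr + rc) if (pr + rc) > 0 else 0.0
        rows.append({"threshold": float(t), "precision": pr, "recall": rc,
                     "f1": f1, "coverage": float(covered.mean())})
    return pd.DataFrame(rows)


def term_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Non-interpolated area under the precision–recall curve for one term.

    Step-wise average precision: precision is accumulated over recall
    increments at each distinct score threshold in descending order, with
    tied scores forming a single step.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("term needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    area = 0.0
    tp = 0
    seen = 0
    prev_recall = 0.0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        seen = j
        recall = tp / n_pos
        precision = tp / seen
        area += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return float(area)


def macro_aupr(scores: np.ndarray, labels: np.ndarray) -> tuple[float, dict]:
    """Macro-average AUPR over terms; terms without both classes are
    skipped and logged."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    per = {}
    for j in range(labels.shape[1]):
        col = labels[:, j]
        if col.sum() in (0, len(col)):
            logger.info("term %d skipped in AUPR (single-class labels)", j)
            continue
        per[j] = term_aupr(scores[:, j], col)
    if not per:
        raise ValueError("no term has both classes; AUPR undefined")
    return float(np.mean(list(per.values()))), per


def bootstrap(metric_fn, scores: np.ndarray, labels: np.ndarray,
              n_boot: int = 100, seed: int = 0) -> dict:
    """Protein-level bootstrap of a metric function ``metric_fn(scores,
    labels) -> float``.  Deterministic given ``seed``."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    vals = []
    n = scores.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(float(metric_fn(scores[idx], labels[idx])))
        except ValueError:
            continue  # degenerate resample (e.g. single-class term)
    vals = np.asarray(vals)
    if not len(vals):
        raise ValueError("all bootstrap replicates were degenerate")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
            if len(vals) > 1 else 0.0,
            "median": float(med), "iqr": (float(q1), float(q3)),
            "n_boot": int(len(vals))}


def evaluate(scores: np.ndarray, labels: np.ndarray, n_boot: int = 0,
             seed: int = 0) -> EvaluationResult:
    """Full evaluation report: Fmax, PR curve, per-term and macro AUPR, and
    optional bootstrap summaries of both headline metrics."""
    fm, t_star = fmax(scores, labels)
    curve = precision_recall_curve(scores, labels)
    macro, per = macro_aupr(scores, labels)
    result = EvaluationResult(fmax=fm, fmax_threshold=t_star, pr_curve=curve,
                              aupr_per_term=per, macro_aupr=macro)
    if n_boot:
        result.bootstrap = {
            "fmax": bootstrap(lambda s, y: fmax(s, y)[0], scores, labels,
                              n_boot=n_boot, seed=seed),
            "macro_aupr": bootstrap(lambda s, y: macro_aupr(s, y)[0], scores,
                                    labels, n_boot=n_boot, seed=seed + 1),
        }
    return result
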