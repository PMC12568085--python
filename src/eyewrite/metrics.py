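"""Classification metrics and the exact Wilcoxon signed-rank test.

Precision, recall and F1 are macro-averaged: each class contributes
equally regardless of support.  Under balanced test classes, macro recall
is algebraically identical to accuracy — a useful sanity check for
leave-one-subject-out reports with balanced designs.

The Wilcoxon signed-rank test compares paired per-subject accuracies of
two configurations.  For small samples the p-value is exact, obtained by
enumerating all 2^m sign assignments of the nonzero differences; for
larger samples a tie-corrected normal approximation with continuity
correction is used.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["compute_metrics", "wilcoxon_signed_rank"]

_EXACT_LIMIT = 20


def compute_metrics(predictions: Sequence, truths: Sequence,
                    class_set: Sequence) -> tuple[float, float, float, float]:
    """Accuracy and macro precision/recall/F1, all in percent.

    Per-class precision/recall with zero denominators count as 0.  A class
    that never occurs in the truths enters the macro average only when it
    is (wrongly) predicted, so untouched classes do not dilute the scores.
    """
    preds = list(predictions)
    trues = list(truths)
    if len(preds) != len(trues) or not preds:
        raise ValueError("predictions and truths must have equal length >= 1")
    classes = list(class_set)
    index = {c: i for i, c in enumerate(classes)}
    for v in preds + trues:
        if v not in index:
            raise ValueError(f"unknown class id {v!r}")

    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)  # [truth, prediction]
    for t, p in zip(trues, preds):
        confusion[index[t], index[p]] += 1

    tp = np.diag(confusion).astype(float)
    support = confusion.sum(axis=1).astype(float)
    predicted = confusion.sum(axis=0).astype(float)

    active = (support > 0) | (predicted > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(predicted > 0, tp / np.maximum(predicted, 1), 0.0)
        rec = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)

    accuracy = tp.sum() / len(trues)
    macro = lambda v: float(v[active].mean())
    return (100.0 * accuracy, 100.0 * macro(prec),
            100.0 * macro(rec), 100.0 * macro(f1))


def _exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-tailed exact p by enumerating all sign assignments.

    The null distribution of W+ is the distribution of the sum of a
    uniformly random subset of the ranks; it is symmetric about
    sum(ranks)/2, so the two-tailed p doubles the smaller tail (capped
    at 1).
    """
    n_assign = 1 << len(ranks)
    # subset sums over sign assignments, built by iterative doubling
    sums = np.array([0.0])
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    ge = np.count_nonzero(sums >= w_plus - 1e-12) / n_assign
    le = np.count_nonzero(sums <= w_plus + 1e-12) / n_assign
    return min(1.0, 2.0 * min(ge, le))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  Exact enumeration is used for up to 20 nonzero
    differences, beyond that a tie-corrected normal approximation with
    continuity correction.  All-zero differences give p = 1 by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("inputs must be 1-D, equal-length, non-empty")
    d = a - b
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m <= _EXACT_LIMIT:
        return _exact_p(w_plus, ranks)
    mean = m * (m + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts ** 3 - counts)).sum()) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    from scipy.stats import norm
    return float(min(1.0, 2.0 * norm.sf(abs(z))))
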