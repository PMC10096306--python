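"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the library:
exhaustive memoized recursion for local alignment, explicit pair loops for
the concordance index, an explicit threshold sweep for the area under the
precision-recall curve, and textbook regression formulas (via scipy /
sklearn) for rm2.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression


def brute_sw(a: str, b: str, scheme) -> float:
    """Best local-alignment score by suffix recursion over all start pairs.

    An alignment is a sequence of match/mismatch and gap columns; a gap of
    length L costs gap_open + (L-1)*gap_extend; the alignment may stop at
    any point and the empty alignment scores 0.
    """
    go, ge = scheme.gap_open, scheme.gap_extend

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        best = 0.0  # stop here
        if i < len(a) and j < len(b):
            best = max(best, scheme.score(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < len(a):
            best = max(best, -(ge if prev == "A" else go) + rec(i + 1, j, "A"))
        if j < len(b):
            best = max(best, -(ge if prev == "B" else go) + rec(i, j + 1, "B"))
        return best

    starts = [rec(i, j, "M") for i in range(len(a)) for j in range(len(b))]
    return max([0.0] + starts)


def brute_concordance(y_true, y_pred) -> float:
    """O(n^2) explicit pair loop; prediction ties score half a win."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    wins = 0.0
    pairs = 0
    for i in range(len(y_true)):
        for j in range(len(y_true)):
            if y_true[i] > y_true[j]:
                pairs += 1
                if y_pred[i] > y_pred[j]:
                    wins += 1.0
                elif y_pred[i] == y_pred[j]:
                    wins += 0.5
    return wins / pairs


def brute_aupr(labels, scores) -> float:
    """Step-wise PR area by explicit sweep over every distinct score."""
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        called = scores >= t
        tp = int((labels[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def oracle_rm2(y_true, y_pred) -> float:
    """rm2 via scipy's Pearson r and sklearn's through-origin regression."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    r2 = stats.pearsonr(y_true, y_pred).statistic ** 2
    fit = LinearRegression(fit_intercept=False).fit(y_true[:, None], y_pred)
    r0_2 = fit.score(y_true[:, None], y_pred)
    return r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))
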