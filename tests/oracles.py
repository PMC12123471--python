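"""Independent brute-force reference implementations used only by tests.

Each function re-derives a metric from its definition by explicit
enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_ece(scores, outcomes, n_bins=10):
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    total = 0.0
    for k in range(n_bins):
        lo, hi = k / n_bins, (k + 1) / n_bins
        if k == n_bins - 1:
            mask = (scores >= lo) & (scores <= hi)
        else:
            mask = (scores >= lo) & (scores < hi)
        if mask.sum() == 0:
            continue
        total += (mask.sum() / scores.size) * abs(
            outcomes[mask].mean() - scores[mask].mean())
    return total


def brute_fnr(scores, outcomes, threshold):
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    if not pos:
        return float("nan")
    return sum(1 for s in pos if s < threshold) / len(pos)


def brute_balanced_accuracy(scores, outcomes, threshold):
    tp = sum(1 for s, y in zip(scores, outcomes) if y == 1 and s >= threshold)
    fn = sum(1 for s, y in zip(scores, outcomes) if y == 1 and s < threshold)
    tn = sum(1 for s, y in zip(scores, outcomes) if y == 0 and s < threshold)
    fp = sum(1 for s, y in zip(scores, outcomes) if y == 0 and s >= threshold)
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def brute_auroc(scores, outcomes):
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    neg = [s for s, y in zip(scores, outcomes) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_auprc(scores, outcomes):
    # precision-weighted sum of recall increments over descending thresholds
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    n_pos = outcomes.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (outcomes == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_wilcoxon(differences):
    """Exact two-sided signed-rank p by full 2^n sign enumeration."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    # midranks of |d|, computed by counting
    absd = np.abs(d)
    ranks = np.array([(absd < v).sum() + ((absd == v).sum() + 1) / 2
                      for v in absd])
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    stat = min(w_pos, w_neg)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= stat + 1e-12:
            count += 1
    p = min(1.0, 2.0 * count / 2 ** n)
    return stat, p
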