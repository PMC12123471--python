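"""Paired nonparametric comparison machinery.

Two-sided Wilcoxon signed-rank tests with the usual zero-difference drop and
midranks for tied magnitudes, and the Holm-Bonferroni step-down adjustment.
For small samples (n <= 25 after zero removal) the signed-rank null is
computed exactly, by dynamic programming over the distribution of W+ on
doubled ranks (doubling makes midranks integral); larger samples use the
normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["wilcoxon_signed_rank", "holm_bonferroni"]

EXACT_LIMIT = 25


def wilcoxon_signed_rank(differences) -> tuple:
    """Two-sided signed-rank test on paired differences.

    Returns ``(statistic, p)`` where the statistic is min(W+, W-).  Zero
    differences are dropped; if all are zero there is no evidence either
    way and p = 1.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    n = d.size
    r = rankdata(np.abs(d))  # midranks
    w_pos = float(r[d > 0].sum())
    w_neg = float(r[d < 0].sum())
    stat = min(w_pos, w_neg)

    if n <= EXACT_LIMIT:
        r2 = np.rint(2 * r).astype(np.int64)  # doubled ranks are integers
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for rr in r2:
            shifted = np.zeros_like(dist)
            shifted[rr:] = dist[:total + 1 - rr]
            dist = dist + shifted
        w2 = int(np.rint(2 * stat))
        p = 2.0 * dist[: w2 + 1].sum() / 2.0 ** n
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(r, return_counts=True)
        tie_term = float(((counts ** 3 - counts)).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (stat - mu + 0.5) / sigma  # continuity correction toward the mean
        p = 2.0 * norm.cdf(z)
    return stat, float(min(p, 1.0))


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment, mapped back to the input order.

    adjusted_(i) = max_{j <= i} (m - j + 1) * p_(j), capped at 1, over the
    ascending order statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
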