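"""Evaluation metrics, overall and per subgroup, plus the multicalibration audit.

Conventions used throughout the package:

* Prediction bins are ``n_bins`` equal-width intervals of [0, 1],
  right-open except the last (``[0.9, 1.0]`` closed at 1).
* ECE is the count-weighted mean over nonempty bins of the absolute gap
  between mean outcome and mean prediction.
* A record is predicted positive iff its score is at or above the threshold;
  FNR is the fraction of true positives scored below it.  A rate with an
  empty denominator is *undefined* and reported as NaN, never raised —
  summaries over groups exclude undefined entries.
* The prevalence of a (group x bin) cell is its size over the full
  evaluation set, the same gamma semantics as the group-level filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .groups import GroupCollection

__all__ = [
    "BinningScheme",
    "AuditReport",
    "expected_calibration_error",
    "false_negative_rate",
    "false_positive_rate",
    "balanced_accuracy",
    "rank_metrics",
    "subgroup_metric_table",
    "audit_multicalibration",
]


@dataclass(frozen=True)
class BinningScheme:
    """Equal-width partition of [0,1] into n_bins prediction intervals."""

    n_bins: int = 10

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")

    def bin_index(self, scores: np.ndarray) -> np.ndarray:
        idx = np.floor(np.asarray(scores, dtype=float) * self.n_bins).astype(np.int64)
        return np.minimum(idx, self.n_bins - 1)  # score 1.0 -> last bin


def _check(scores, outcomes):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes differ in length")
    if s.size == 0:
        raise ValueError("empty input")
    if np.isnan(s).any():
        raise ValueError("NaN score")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores outside [0, 1]")
    return s, y.astype(np.int64)


def expected_calibration_error(scores, outcomes,
                               binning: BinningScheme = BinningScheme(),
                               aggregate: str = "mean") -> float:
    """Binned ECE.  ``aggregate='max'`` gives the worst-bin residual instead
    of the count-weighted mean (sensitivity-check variant)."""
    s, y = _check(scores, outcomes)
    b = binning.bin_index(s)
    n = s.size
    resid, weights = [], []
    for k in np.unique(b):
        m = b == k
        resid.append(abs(y[m].mean() - s[m].mean()))
        weights.append(m.sum() / n)
    if aggregate == "max":
        return float(max(resid))
    return float(np.dot(weights, resid))


def false_negative_rate(scores, outcomes, threshold: float = 0.5,
                        prior_strength: float = 0.0,
                        prior_rate: float = 0.0) -> float:
    """FNR = P(score < threshold | y = 1); NaN when there are no positives.

    ``prior_strength``/``prior_rate`` enable an optional smoothed estimate
    (FN + c*pi) / (P + c), off by default.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    pos = y.sum()
    fn = int(((s < threshold) & y).sum())
    if prior_strength > 0:
        return (fn + prior_strength * prior_rate) / (pos + prior_strength)
    if pos == 0:
        return float("nan")
    return fn / pos


def false_positive_rate(scores, outcomes, threshold: float = 0.5) -> float:
    """FPR = P(score >= threshold | y = 0); NaN when there are no negatives."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    neg = (~y).sum()
    if neg == 0:
        return float("nan")
    return int(((s >= threshold) & ~y).sum()) / neg


def balanced_accuracy(scores, outcomes, threshold: float = 0.5) -> float:
    """(sensitivity + specificity) / 2 at the threshold."""
    y = np.asarray(outcomes).astype(bool)
    if y.all() or not y.any():
        raise ValueError("balanced accuracy needs both classes")
    sens = 1.0 - false_negative_rate(scores, outcomes, threshold)
    spec = 1.0 - false_positive_rate(scores, outcomes, threshold)
    return (sens + spec) / 2.0


def rank_metrics(scores, outcomes) -> tuple:
    """(AUROC, AUPRC); AUROC counts ties as half, AUPRC is the
    precision-weighted sum of recall increments."""
    y = np.asarray(outcomes).astype(np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("rank metrics need both classes")
    return (float(roc_auc_score(y, scores)),
            float(average_precision_score(y, scores)))


def subgroup_metric_table(scores, outcomes, collection: GroupCollection,
                          binning: BinningScheme = BinningScheme(),
                          threshold: float = 0.5) -> pd.DataFrame:
    """Per-group ECE / FNR / FPR with counts, plus overall and summary rows.

    Rows are indexed by group label; ``overall`` covers all records,
    ``mean_over_groups`` and ``max_over_groups`` summarize the group rows
    excluding undefined (NaN) entries.
    """
    s, y = _check(scores, outcomes)

    def row(mask):
        sm, ym = s[mask], y[mask]
        ece = expected_calibration_error(sm, ym, binning) if sm.size else float("nan")
        return {
            "ece": ece,
            "fnr": false_negative_rate(sm, ym, threshold) if sm.size else float("nan"),
            "fpr": false_positive_rate(sm, ym, threshold) if sm.size else float("nan"),
            "count": int(mask.sum()),
            "positives": int(ym.sum()),
        }

    rows = {"overall": row(np.ones(s.size, dtype=bool))}
    for g in collection.groups:
        rows[g.label] = row(collection.membership[g.label])

    table = pd.DataFrame.from_dict(rows, orient="index")
    group_part = table.drop(index="overall")
    if len(group_part):
        for name, fn in (("mean_over_groups", np.nanmean),
                         ("max_over_groups", np.nanmax)):
            summ = {m: float(fn(group_part[m].to_numpy()))
                    if not np.isnan(group_part[m].to_numpy()).all() else float("nan")
                    for m in ("ece", "fnr", "fpr")}
            summ["count"] = int(group_part["count"].sum())
            summ["positives"] = int(group_part["positives"].sum())
            table.loc[name] = summ
    table.index.name = "group"
    return table


@dataclass
class AuditReport:
    """Cells violating the alpha-multicalibration constraint.

    A model is (alpha, gamma)-multicalibrated on the data when, in every
    (group x prediction-bin) cell holding at least a gamma fraction of all
    records, the mean outcome and mean prediction differ by at most alpha.
    ``violations`` lists exactly the offending cells.
    """

    alpha: float
    gamma: float
    violations: list = field(default_factory=list)
    # each violation: dict(group, bin, size, prevalence, delta)

    @property
    def multicalibrated(self) -> bool:
        return not self.violations

    def to_frame(self) -> pd.DataFrame:
        cols = ["group", "bin", "size", "prevalence", "delta"]
        return pd.DataFrame(self.violations, columns=cols)


def audit_multicalibration(scores, outcomes, collection: GroupCollection,
                           binning: BinningScheme = BinningScheme(),
                           alpha: float = 0.01, gamma: float = 0.001
                           ) -> AuditReport:
    """Enumerate every (group, bin) cell and report those with prevalence
    >= gamma whose calibration residual exceeds alpha in magnitude."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    s, y = _check(scores, outcomes)
    n = s.size
    bins = binning.bin_index(s)
    report = AuditReport(alpha=alpha, gamma=gamma)
    for g in collection.groups:
        gm = collection.membership[g.label]
        for k in range(binning.n_bins):
            cell = gm & (bins == k)
            size = int(cell.sum())
            if size == 0 or size / n < gamma:
                continue
            delta = float(y[cell].mean() - s[cell].mean())
            if abs(delta) > alpha:
                report.violations.append({
                    "group": g.label, "bin": k, "size": size,
                    "prevalence": size / n, "delta": delta,
                })
    return report
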