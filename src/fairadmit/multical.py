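"""Multicalibration boosting: iterative subgroup calibration repair.

The postprocessor sweeps over every (group x prediction-bin) cell of a group
collection and, whenever a sufficiently prevalent cell's mean prediction
deviates from its mean outcome by more than ``alpha``, shifts the cell
members' scores by the residual (times a damping ``step``), clipping to
[0, 1].  Sweeps repeat until a full pass makes no update; the fitted object
stores the ordered update list so the exact same repair can be replayed on
held-out predictions.

Bins are recomputed against the *current* scores during both fit and replay:
a record moved to a new bin by an earlier update is not touched by a later
update targeting its old bin.  This is the contract that makes replay
well-defined — replaying the updates on the fit data reproduces the fitted
scores bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .groups import GroupCollection
from .metrics import AuditReport, BinningScheme, audit_multicalibration

__all__ = ["MulticalibConfig", "CalibrationUpdate", "Postprocessor",
           "fit_multicalibration", "apply_postprocessor"]


@dataclass(frozen=True)
class MulticalibConfig:
    """alpha: per-cell calibration bound; gamma: minimum cell prevalence;
    step: update damping in (0, 1]; sweep_order 'canonical' or 'random'."""

    alpha: float = 0.01
    gamma: float = 0.001
    binning: BinningScheme = BinningScheme(10)
    max_sweeps: int = 100
    step: float = 1.0
    sweep_order: str = "canonical"
    order_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 < self.step <= 1.0:
            raise ValueError("step must be in (0, 1]")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be positive")


@dataclass(frozen=True)
class CalibrationUpdate:
    group: str
    bin: int
    delta: float
    sweep: int


@dataclass
class Postprocessor:
    config: MulticalibConfig
    updates: list = field(default_factory=list)
    converged: bool = True
    fit_audit: AuditReport | None = None

    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.config.alpha,
            "gamma": self.config.gamma,
            "n_bins": self.config.binning.n_bins,
            "step": self.config.step,
            "converged": self.converged,
            "updates": [{"group": u.group, "bin": u.bin, "delta": u.delta,
                         "sweep": u.sweep} for u in self.updates],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Postprocessor":
        doc = json.loads(text)
        cfg = MulticalibConfig(alpha=doc["alpha"], gamma=doc["gamma"],
                               binning=BinningScheme(doc["n_bins"]),
                               step=doc["step"])
        ups = [CalibrationUpdate(u["group"], u["bin"], u["delta"], u["sweep"])
               for u in doc["updates"]]
        return cls(cfg, ups, doc["converged"])


def _apply_update(scores, cell, delta, step):
    # single shared code path for fit and replay: identical float ops
    scores[cell] = np.clip(scores[cell] + step * delta, 0.0, 1.0)


def fit_multicalibration(scores, outcomes, collection: GroupCollection,
                         config: MulticalibConfig = MulticalibConfig()
                         ) -> tuple:
    """Learn and apply calibration updates on the fit data.

    Returns ``(Postprocessor, adjusted_scores)``.  With an empty collection
    the postprocessor is the identity.  On convergence the stored fit-set
    audit is violation-free at (alpha, gamma) — the calibration certificate.
    """
    s = np.asarray(scores, dtype=float).copy()
    y = np.asarray(outcomes).astype(np.int64)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes differ in length")
    if s.size and (np.isnan(s).any() or ((s < 0) | (s > 1)).any()):
        raise ValueError("scores must be probabilities in [0, 1]")
    cfg = config
    post = Postprocessor(cfg, [], True, None)
    if not collection.groups:
        post.fit_audit = AuditReport(cfg.alpha, cfg.gamma)
        return post, s

    n = s.size
    order_rng = np.random.default_rng(cfg.order_seed)
    base_order = sorted(collection.labels)
    converged = False
    for sweep in range(cfg.max_sweeps):
        labels = list(base_order)
        if cfg.sweep_order == "random":
            order_rng.shuffle(labels)
        changed = False
        for label in labels:
            gm = collection.membership[label]
            for k in range(cfg.binning.n_bins):
                cell = gm & (cfg.binning.bin_index(s) == k)
                size = int(cell.sum())
                if size == 0 or size / n < cfg.gamma:
                    continue
                delta = float(y[cell].mean() - s[cell].mean())
                if abs(delta) > cfg.alpha:
                    _apply_update(s, cell, delta, cfg.step)
                    post.updates.append(CalibrationUpdate(label, k, delta, sweep))
                    changed = True
        if not changed:
            converged = True
            break
    post.converged = converged
    if not converged:
        warnings.warn(f"multicalibration did not converge in {cfg.max_sweeps} "
                      "sweeps; returning partially repaired scores")
    post.fit_audit = audit_multicalibration(
        s, y, collection, cfg.binning, cfg.alpha, cfg.gamma)
    return post, s


def apply_postprocessor(post: Postprocessor, scores,
                        memberships: dict) -> np.ndarray:
    """Replay the fitted updates, in recorded order, on new predictions.

    ``memberships`` maps group label -> boolean vector over the new records
    (``GroupCollection.rebind(...).membership`` for a test split).
    """
    s = np.asarray(scores, dtype=float).copy()
    cfg = post.config
    for u in post.updates:
        if u.group not in memberships:
            raise KeyError(f"fitted update references unknown group {u.group!r}")
        cell = memberships[u.group] & (cfg.binning.bin_index(s) == u.bin)
        if cell.any():
            _apply_update(s, cell, u.delta, cfg.step)
    return s
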