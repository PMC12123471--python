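"""Paired comparison harness: scenarios x fairness tasks x trials.

Each trial draws one seeded 50/50 train/test split, tunes the base learner
on the training half (successive-halving grid search, 3-fold stratified CV,
balanced accuracy), applies the scenario's debiasing — multicalibration
postprocessing fitted on train and replayed on test for the calibration
task, the multiobjective weight search for the FNR task, nothing for the
base scenario — and evaluates on the held-out half.

Evaluation is always over the *intersectional* group collection, whatever
collection the debiasing itself used: the question the harness answers is
how much fairness optimized on marginal groups transfers to intersectional
ones.  The intersectional evaluation collection is built and
prevalence-filtered on the full dataset before splitting, so the group list
is identical across trials and scenarios.  Trial t of every scenario shares
the same split seed, giving paired samples for the signed-rank tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import ConfigError
from .fomo import FomoConfig, optimize, select_solution
from .groups import GroupCollection, build_collection, prevalence_filter
from .learners import LearnerSpec, design_matrix, predict_risk, tune_learner
from .metrics import BinningScheme, rank_metrics, subgroup_metric_table
from .multical import MulticalibConfig, apply_postprocessor, fit_multicalibration
from .stats import holm_bonferroni, wilcoxon_signed_rank

logger = logging.getLogger("fairadmit")

__all__ = ["ScenarioSpec", "TrialResult", "run_trial", "run_experiment",
           "trials_frame", "summarize_report"]

_RETRY_OFFSET = 10_000_019  # derived-seed stream for degenerate-split retries


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the experimental grid."""

    scenario: str = "base"             # base | single:<attr> | marginal | intersectional
    task: str = "calibration"          # calibration | fnr
    learner: LearnerSpec = LearnerSpec()
    n_trials: int = 100
    split_fraction: float = 0.5
    base_seed: int = 0
    alpha: float = 0.01
    gamma: float = 0.001
    threshold: float = 0.5
    binning: BinningScheme = BinningScheme(10)
    fomo: FomoConfig | None = None
    # fairness-forward selection, matching the worst-case objective; the
    # knee policy is the conservative alternative when overall accuracy
    # must be protected more tightly
    selection_policy: str = "min_fairness"
    name: str = ""

    def __post_init__(self):
        if self.task not in ("calibration", "fnr"):
            raise ConfigError(f"unknown fairness task {self.task!r}")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be at least 1")
        if not self.name:
            object.__setattr__(self, "name", f"{self.task}:{self.scenario}")


@dataclass
class TrialResult:
    name: str
    scenario: str
    task: str
    trial: int
    seed: int
    metric_table: pd.DataFrame         # test-half metrics, intersectional groups
    auroc: float
    auprc: float
    converged: bool = True
    n_test: int = 0


def _split(data: pd.DataFrame, frac: float, seed: int, max_retries: int = 5):
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt * _RETRY_OFFSET)
        perm = rng.permutation(len(data))
        n_train = int(round(len(data) * frac))
        tr, te = perm[:n_train], perm[n_train:]
        ytr = data["admitted"].to_numpy()[tr]
        yte = data["admitted"].to_numpy()[te]
        if 0 < ytr.sum() < len(ytr) and 0 < yte.sum() < len(yte):
            if attempt:
                logger.warning("degenerate split at seed %d; retried", seed)
            return data.iloc[tr], data.iloc[te]
    raise RuntimeError("could not draw a split with both classes on each side")


def _eval_collection(data: pd.DataFrame, protected, gamma) -> GroupCollection:
    return prevalence_filter(
        build_collection(data, list(protected), "intersectional"), gamma)


def run_trial(data: pd.DataFrame, spec: ScenarioSpec, trial_seed: int,
              eval_collection: GroupCollection | None = None,
              trial_index: int = 0) -> TrialResult:
    """Run one seeded trial and return test-half metrics.

    ``eval_collection`` (intersectional groups on the full data) may be
    passed in to avoid rebuilding it for every trial; it is rebound to the
    test rows before any metric is computed, so no metric touches a
    training row.
    """
    protected = spec.learner.protected
    if eval_collection is None:
        eval_collection = _eval_collection(data, protected, spec.gamma)
    train, test = _split(data, spec.split_fraction, trial_seed)
    assert not set(train.index) & set(test.index)

    seed32 = int(trial_seed % 2**31)
    Xtr = design_matrix(spec.learner, train)
    Xte = design_matrix(spec.learner, test)
    ytr = train["admitted"].to_numpy()
    yte = test["admitted"].to_numpy()

    converged = True
    if spec.task == "fnr" and spec.scenario != "base":
        debias = prevalence_filter(
            build_collection(data, list(protected), spec.scenario), spec.gamma)
        fomo_cfg = spec.fomo or FomoConfig()
        fomo_cfg = replace(fomo_cfg, learner=spec.learner,
                           threshold=spec.threshold, seed=seed32)
        front = optimize(train, debias.rebind(train), fomo_cfg,
                         eval_collection=eval_collection)
        _, model = select_solution(front, spec.selection_policy)
        scores_te = predict_risk(model, Xte)
    else:
        model = tune_learner(spec.learner, Xtr, ytr, seed32)
        scores_te = predict_risk(model, Xte)
        if spec.task == "calibration" and spec.scenario != "base":
            debias = prevalence_filter(
                build_collection(data, list(protected), spec.scenario),
                spec.gamma)
            mc = MulticalibConfig(alpha=spec.alpha, gamma=spec.gamma,
                                  binning=spec.binning)
            scores_tr = predict_risk(model, Xtr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post, _ = fit_multicalibration(
                    scores_tr, ytr, debias.rebind(train), mc)
            converged = post.converged
            scores_te = apply_postprocessor(
                post, scores_te, debias.rebind(test).membership)

    table = subgroup_metric_table(scores_te, yte, eval_collection.rebind(test),
                                  spec.binning, spec.threshold)
    auroc, auprc = rank_metrics(scores_te, yte)
    return TrialResult(spec.name, spec.scenario, spec.task, trial_index,
                       trial_seed, table, auroc, auprc, converged, len(test))


def run_experiment(data: pd.DataFrame, specs: list) -> list:
    """All trials of all scenario specs, with splits paired across specs.

    Every spec must share ``n_trials`` and ``base_seed``; trial t of every
    spec uses split seed ``base_seed + t``.
    """
    if not specs:
        return []
    if len({(s.n_trials, s.base_seed) for s in specs}) != 1:
        raise ConfigError("all specs must share n_trials and base_seed to pair")
    protected = specs[0].learner.protected
    gamma = specs[0].gamma
    eval_coll = _eval_collection(data, protected, gamma)
    results = []
    for t in range(specs[0].n_trials):
        seed = specs[0].base_seed + t
        for spec in specs:
            logger.info("trial %d / %d: %s", t + 1, spec.n_trials, spec.name)
            results.append(run_trial(data, spec, seed, eval_coll, t))
    return results


def trials_frame(results: list) -> pd.DataFrame:
    """Tidy long-format table of per-trial summary metrics."""
    rows = []
    for r in results:
        summary = (r.metric_table.loc["mean_over_groups"]
                   if "mean_over_groups" in r.metric_table.index
                   else r.metric_table.loc["overall"])
        rows.append({
            "name": r.name, "scenario": r.scenario, "task": r.task,
            "trial": r.trial, "seed": r.seed,
            "mean_group_ece": summary["ece"], "mean_group_fnr": summary["fnr"],
            "max_group_ece": (r.metric_table.loc["max_over_groups", "ece"]
                              if "max_over_groups" in r.metric_table.index
                              else np.nan),
            "max_group_fnr": (r.metric_table.loc["max_over_groups", "fnr"]
                              if "max_over_groups" in r.metric_table.index
                              else np.nan),
            "overall_ece": r.metric_table.loc["overall", "ece"],
            "overall_fnr": r.metric_table.loc["overall", "fnr"],
            "auroc": r.auroc, "auprc": r.auprc, "converged": r.converged,
        })
    return pd.DataFrame(rows)


def summarize_report(results: list, pairs: list,
                     metric: str = "mean_group_ece") -> pd.DataFrame:
    """Paired signed-rank comparisons with Holm adjustment over the pairs.

    ``pairs`` is a list of (name_a, name_b) spec names; for each, the
    per-trial differences a - b of the chosen summary metric are tested.
    Holm-Bonferroni is applied across all pairs in this one report.
    """
    frame = trials_frame(results)
    raws, rows = [], []
    for a, b in pairs:
        fa = frame[frame["name"] == a].set_index("trial")[metric]
        fb = frame[frame["name"] == b].set_index("trial")[metric]
        if len(fa) == 0 or not fa.index.equals(fb.index):
            raise ConfigError(f"unpaired trials for comparison {a!r} vs {b!r}")
        diffs = (fa - fb).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = wilcoxon_signed_rank(diffs)
        raws.append(p)
        rows.append({"scenario_a": a, "scenario_b": b, "metric": metric,
                     "n_trials": len(diffs), "mean_a": float(fa.mean()),
                     "mean_b": float(fb.mean()),
                     "mean_difference": float(np.mean(diffs)),
                     "statistic": stat, "p_raw": p})
    adj = holm_bonferroni(raws) if raws else []
    report = pd.DataFrame(rows)
    report["p_holm"] = adj
    report["significant"] = report["p_holm"] <= 0.05
    return report
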