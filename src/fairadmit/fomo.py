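"""Fairness-oriented multiobjective training of the admission model.

Rather than a single fairness-penalized loss, the trainer searches over
group-indexed sample-weight multipliers for the base learner, treating
overall error (1 - balanced accuracy) and worst-case intersectional
subgroup false-negative rate as two separate objectives.  The search is a
seeded elitist evolutionary loop over box-constrained real genomes:
nondominated sorting with crowding-distance diversity, simulated binary
crossover and polynomial mutation.  The all-ones genome — the unweighted
base learner — is always injected into the initial population, so the
returned Pareto front can never lose to the baseline on the fairness axis.

The fairness objective is always measured on the *intersectional* group
collection, even when the weight knobs are indexed by marginal groups:
that asymmetry is exactly the marginal-vs-intersectional comparison the
experiment harness is built to make.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .groups import GroupCollection
from .learners import LearnerSpec, design_matrix, make_estimator, predict_risk
from .metrics import balanced_accuracy, false_negative_rate

__all__ = ["FomoConfig", "ParetoFront", "evaluate_genome", "optimize",
           "select_solution", "genome_weights"]


@dataclass(frozen=True)
class FomoConfig:
    population: int = 50
    generations: int = 50
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1/n_genes
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    w_min: float = 0.1
    w_max: float = 10.0
    val_fraction: float = 0.25
    seed: int = 0
    learner: LearnerSpec = LearnerSpec()
    threshold: float = 0.5
    # Beta(c*pi, c*(1-pi)) shrinkage of group FNRs inside the fairness
    # objective, pi = training outcome prevalence.  With a handful of
    # positives a raw group FNR is 0/1-valued and can pin the worst-case
    # objective at a flat 1.0; mild shrinkage keeps it informative.
    # Reported metrics are never smoothed.
    fnr_prior_strength: float = 2.0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class ParetoFront:
    """Nondominated (error, fairness) solutions with their weight genomes."""

    genomes: np.ndarray        # (k, n_genes)
    objectives: np.ndarray     # (k, 2): (1 - bal. accuracy, max subgroup FNR)
    group_labels: list
    provenance: dict = field(default_factory=dict)
    _refit: object = None      # closure refitting a genome on the full train set

    def __len__(self):
        return len(self.genomes)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"w[{lab}]": self.genomes[:, i]
                for i, lab in enumerate(self.group_labels)}
        cols["error_objective"] = self.objectives[:, 0]
        cols["fairness_objective"] = self.objectives[:, 1]
        return pd.DataFrame(cols)


def genome_weights(genome: np.ndarray, collection: GroupCollection,
                   n_records: int) -> np.ndarray:
    """Per-record sample weights: the product of the multipliers of every
    group containing the record; records in no group keep weight 1.  With an
    empty collection the single gene is a global weight."""
    w = np.ones(n_records, dtype=float)
    if not collection.groups:
        return w * float(np.asarray(genome).ravel()[0])
    for i, g in enumerate(collection.groups):
        w[collection.membership[g.label]] *= genome[i]
    return w


def _objectives(genome, train, val, weight_collection, eval_collection,
                learner: LearnerSpec, threshold: float, seed: int,
                fnr_prior_strength: float = 0.0):
    ytr = train["admitted"].to_numpy()
    w = genome_weights(np.asarray(genome, dtype=float), weight_collection,
                       len(train))
    try:
        Xtr = design_matrix(learner, train)
        est = make_estimator(learner, seed)
        est.fit(Xtr, ytr, sample_weight=w)
        scores = predict_risk(est, design_matrix(learner, val))
    except Exception as exc:  # noqa: BLE001 — worst fitness, not a crash
        warnings.warn(f"base learner failed ({exc}); assigning worst fitness")
        return 1.0, 1.0
    yval = val["admitted"].to_numpy()
    err = 1.0 - balanced_accuracy(scores, yval, threshold)
    prior_rate = float(train["admitted"].mean())
    memb = eval_collection.rebind(val).membership
    fnrs = []
    for m in memb.values():
        if not m.any() or yval[m].sum() == 0:
            continue  # no positives: undefined, excluded from the max
        fnrs.append(false_negative_rate(
            scores[m], yval[m], threshold,
            prior_strength=fnr_prior_strength, prior_rate=prior_rate))
    fair = max(fnrs) if fnrs else 0.0
    return float(err), float(fair)


def evaluate_genome(genome, train: pd.DataFrame, val: pd.DataFrame,
                    weight_collection: GroupCollection,
                    eval_collection: GroupCollection,
                    learner: LearnerSpec = LearnerSpec(),
                    threshold: float = 0.5, seed: int = 0,
                    fnr_prior_strength: float = 0.0) -> tuple:
    """(1 - balanced accuracy, max defined subgroup FNR) on the validation
    split, for a learner fitted with this genome's sample weights.
    Validation groups without positives are excluded from the max;
    ``fnr_prior_strength`` applies the trainer's FNR shrinkage."""
    genome = np.asarray(genome, dtype=float).ravel()
    dim = max(len(weight_collection.groups), 1)
    if genome.size != dim:
        raise ValueError(f"genome has {genome.size} genes, collection needs {dim}")
    return _objectives(genome, train, val, weight_collection, eval_collection,
                       learner, threshold, seed, fnr_prior_strength)


# --- NSGA-II machinery ------------------------------------------------------


def _nondominated_sort(F: np.ndarray) -> list:
    n = len(F)
    dominates = [[] for _ in range(n)]
    dominated_by = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if (F[i] <= F[j]).all() and (F[i] < F[j]).any():
                dominates[i].append(j)
                dominated_by[j] += 1
            elif (F[j] <= F[i]).all() and (F[j] < F[i]).any():
                dominates[j].append(i)
                dominated_by[i] += 1
    fronts = [[i for i in range(n) if dominated_by[i] == 0]]
    while fronts[-1]:
        nxt = []
        for i in fronts[-1]:
            for j in dominates[i]:
                dominated_by[j] -= 1
                if dominated_by[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
    return fronts[:-1]


def _crowding(F: np.ndarray, idx: list) -> np.ndarray:
    k = len(idx)
    d = np.zeros(k)
    if k <= 2:
        return np.full(k, np.inf)
    sub = F[idx]
    for m in range(F.shape[1]):
        order = np.argsort(sub[:, m], kind="stable")
        d[order[0]] = d[order[-1]] = np.inf
        span = sub[order[-1], m] - sub[order[0], m]
        if span > 0:
            d[order[1:-1]] += (sub[order[2:], m] - sub[order[:-2], m]) / span
    return d


def _sbx(a, b, lo, hi, eta, rng):
    u = rng.random(a.shape)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
    c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(x, lo, hi, eta, prob, rng):
    y = x.copy()
    do = rng.random(x.shape) < prob
    u = rng.random(x.shape)
    span = hi - lo
    left = (2 * u) ** (1 / (eta + 1)) - 1
    right = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
    delta = np.where(u < 0.5, left, right)
    y[do] = np.clip(x[do] + delta[do] * span, lo, hi)
    return y


def optimize(train: pd.DataFrame, weight_collection: GroupCollection,
             config: FomoConfig,
             eval_collection: GroupCollection | None = None) -> ParetoFront:
    """Run the seeded multiobjective search and return the nondominated set.

    ``train`` is split internally (stratified by outcome) into a fitting part
    and a validation part on which both objectives are scored, so weightings
    that merely overfit the fitting part are not rewarded.  Identical
    (data, config) and seed give an identical front.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if eval_collection is None:
        eval_collection = weight_collection
    dim = max(len(weight_collection.groups), 1)
    pmut = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / dim

    fit_part, val_part = train_test_split(
        train, test_size=cfg.val_fraction, random_state=int(cfg.seed % 2**31),
        stratify=train["admitted"])
    wc_fit = weight_collection.rebind(fit_part)
    cache: dict = {}

    def f(genome: np.ndarray) -> tuple:
        key = genome.tobytes()
        if key not in cache:
            cache[key] = _objectives(genome, fit_part, val_part, wc_fit,
                                     eval_collection, cfg.learner,
                                     cfg.threshold, int(cfg.seed % 2**31),
                                     cfg.fnr_prior_strength)
        return cache[key]

    pop = rng.uniform(cfg.w_min, cfg.w_max, size=(cfg.population, dim))
    pop[0] = 1.0  # the unweighted base learner is always a candidate
    F = np.array([f(g) for g in pop])

    for _ in range(cfg.generations):
        fronts = _nondominated_sort(F)
        rank = np.empty(len(pop), dtype=int)
        crowd = np.empty(len(pop))
        for r, idx in enumerate(fronts):
            rank[idx] = r
            crowd[idx] = _crowding(F, idx)

        def tournament():
            i, j = rng.integers(0, len(pop), size=2)
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        children = []
        while len(children) < cfg.population:
            a, b = pop[tournament()], pop[tournament()]
            if rng.random() < cfg.crossover_prob:
                c1, c2 = _sbx(a, b, cfg.w_min, cfg.w_max, cfg.eta_crossover, rng)
            else:
                c1, c2 = a.copy(), b.copy()
            children.append(_poly_mutation(c1, cfg.w_min, cfg.w_max,
                                           cfg.eta_mutation, pmut, rng))
            if len(children) < cfg.population:
                children.append(_poly_mutation(c2, cfg.w_min, cfg.w_max,
                                               cfg.eta_mutation, pmut, rng))
        children = np.array(children)
        Fc = np.array([f(g) for g in children])

        # elitist environmental selection on parents + offspring
        allpop = np.vstack([pop, children])
        allF = np.vstack([F, Fc])
        keep = []
        for idx in _nondominated_sort(allF):
            if len(keep) + len(idx) <= cfg.population:
                keep.extend(idx)
            else:
                c = _crowding(allF, idx)
                order = np.argsort(-c, kind="stable")
                keep.extend(np.asarray(idx)[order[:cfg.population - len(keep)]])
                break
        pop, F = allpop[keep], allF[keep]

    front_idx = _nondominated_sort(F)[0]
    # deduplicate identical genomes for a clean front
    seen, uniq = set(), []
    for i in sorted(front_idx, key=lambda i: tuple(F[i])):
        key = pop[i].tobytes()
        if key not in seen:
            seen.add(key)
            uniq.append(i)

    def refit(genome):
        est = make_estimator(cfg.learner, int(cfg.seed % 2**31))
        X = design_matrix(cfg.learner, train)
        w = genome_weights(genome, weight_collection, len(train))
        est.fit(X, train["admitted"].to_numpy(), sample_weight=w)
        return est

    return ParetoFront(
        genomes=pop[uniq], objectives=F[uniq],
        group_labels=(weight_collection.labels or ["global"]),
        provenance={"seed": cfg.seed, "population": cfg.population,
                    "generations": cfg.generations,
                    "scenario": weight_collection.scenario},
        _refit=refit)


def select_solution(front: ParetoFront, policy: str = "min_fairness") -> tuple:
    """Pick one solution off the front, deterministically.

    ``min_fairness``: smallest fairness objective, ties by smaller error.
    ``knee``: after min-max normalizing both axes over the front, the
    solution closest (Euclidean) to the ideal point (0, 0).
    Returns (genome, fitted model refit on the full training set).
    """
    if len(front) == 0:
        raise ValueError("empty Pareto front")
    obj = front.objectives
    if policy == "min_fairness":
        order = np.lexsort((obj[:, 0], obj[:, 1]))
        i = int(order[0])
    elif policy == "knee":
        lo, hi = obj.min(axis=0), obj.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        norm = (obj - lo) / span
        i = int(np.argmin(np.hypot(norm[:, 0], norm[:, 1])))
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    genome = front.genomes[i]
    model = front._refit(genome) if front._refit is not None else None
    return genome, model
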